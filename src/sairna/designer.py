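"""Hairpin construction for saiRNA and shRNA silencing reagents.

Two precursor architectures are supported:

* **saiRNA** (single-stranded, Ago2-processed interfering RNA): a short
  16-18 bp stem whose 5' arm carries the guide strand, a 4-nt loop that is
  complementary to the target transcript, a fixed 5' adenosine (pol III
  initiation + Ago loading preference) and an engineered C/A mismatch on
  the 3' arm opposite guide position 1.  Maturation is Dicer-independent:
  Ago2 slices the 3' arm and the passenger strand is destroyed.
* **shRNA**: a >=21 bp stem processed by Dicer into a conventional siRNA
  duplex, built either classically (sense arm 5', guide arm 3', generic
  loop) or with the guide in the 5' arm using the same 5'-A / mismatch
  rules as saiRNA.

Target windows are enumerated directly on the mRNA: the window consumes
``stem_len + loop_len`` nucleotides so that guide positions
2..(stem+loop) are exactly complementary to the target, with position 1
fixed as A whether or not it pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .seqcore import NucSeq, SeqRecord, is_wc_pair, revcomp

logger = logging.getLogger(__name__)

SAIRNA_STEM_RANGE = (16, 18)
SHRNA_5ARM_STEM_RANGE = (21, 24)
STEM_RANGE = (14, 24)
LOOP_RANGE = (2, 9)

#: Default loop for classically designed shRNA (guide in the 3' arm); the
#: widely used TRC/pLKO.1 loop, not target-complementary.
TRC_LOOP = "CUCGAG"


class GuideArm(str, Enum):
    FIVE = "FIVE"
    THREE = "THREE"


class DesignError(ValueError):
    """Raised when a construction rule cannot be satisfied."""


class CategoryError(DesignError):
    """Raised when a builder is called with a stem length it does not own."""


@dataclass
class DesignConstraints:
    """Tunable construction parameters.

    ``max_homopolymer`` is the longest run of one base tolerated in the
    guide; the default of 3 rejects guides with >=4 consecutive U, which
    would embed a premature pol III terminator, and equally long runs of
    other bases that complicate synthesis.
    """

    stem_len: int = 17
    loop_len: int = 4
    guide_arm: GuideArm = GuideArm.FIVE
    first_nt: str = "A"
    mismatch_base: str = "C"
    gc_min: float = 0.25
    gc_max: float = 0.75
    max_homopolymer: int = 3
    loop_complementary: bool = True

    def __post_init__(self) -> None:
        if not STEM_RANGE[0] <= self.stem_len <= STEM_RANGE[1]:
            raise ValueError(f"stem_len must be in {STEM_RANGE}, got {self.stem_len}")
        if not LOOP_RANGE[0] <= self.loop_len <= LOOP_RANGE[1]:
            raise ValueError(f"loop_len must be in {LOOP_RANGE}, got {self.loop_len}")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min > gc_max")
        if self.mismatch_base not in ("C", "A"):
            raise ValueError("mismatch_base must be C or A")

    @property
    def window_len(self) -> int:
        return self.stem_len + self.loop_len


@dataclass(frozen=True)
class TargetSite:
    """A candidate window on the target mRNA (1-based inclusive start)."""

    source_id: str
    start: int
    window: NucSeq  # RNA alphabet, length = stem_len + loop_len
    gc: float


@dataclass(frozen=True)
class GuideStrand:
    seq: NucSeq
    pos1_forced: bool  # True when the fixed 5' A does not pair the target


@dataclass
class HairpinDesign:
    """A designed precursor: 5' arm, loop, 3' arm (all RNA, 5'->3').

    ``mismatches`` holds 1-based stem positions (numbered along the 5'
    arm) that are deliberately unpaired; the engineered mismatch opposite
    guide position 1 lives at stem position 1.  The mismatched terminal
    position still counts toward ``stem_len``.
    """

    arm5: NucSeq
    loop: NucSeq
    arm3: NucSeq
    guide_arm: GuideArm
    mismatches: frozenset[int]
    stem_len: int
    loop_len: int
    site: TargetSite | None = None

    def __post_init__(self) -> None:
        if len(self.arm5) != len(self.arm3) or len(self.arm5) != self.stem_len:
            raise DesignError("arm lengths must both equal stem_len")
        if len(self.loop) != self.loop_len:
            raise DesignError("loop length mismatch")
        for i in range(1, self.stem_len + 1):
            a = self.arm5[i - 1]
            b = self.arm3[self.stem_len - i]
            paired = is_wc_pair(a, b, "RNA")
            if i in self.mismatches and paired:
                raise DesignError(f"declared mismatch at stem position {i} pairs")
            if i not in self.mismatches and not paired:
                raise DesignError(f"stem position {i} is not Watson-Crick paired")

    @property
    def core(self) -> NucSeq:
        """Full hairpin transcript core: arm5 + loop + arm3."""
        return NucSeq(
            self.arm5.residues + self.loop.residues + self.arm3.residues, "RNA"
        )

    @property
    def guide(self) -> NucSeq:
        """The guide strand as designed (before 3' trimming).

        For 5'-arm designs the guide runs from the transcript 5' end
        through the loop; for classical designs it is the 3' arm.
        """
        if self.guide_arm is GuideArm.FIVE:
            return NucSeq(self.arm5.residues + self.loop.residues, "RNA")
        return self.arm3

    @property
    def passenger(self) -> NucSeq:
        return self.arm3 if self.guide_arm is GuideArm.FIVE else self.arm5


@dataclass
class OligoPair:
    """Annealable DNA oligos that reconstruct the cloning insert."""

    top: NucSeq
    bottom: NucSeq
    vector: str
    enzymes: tuple[str, str]
    terminator_len: int
    insert: NucSeq  # double-stranded region between the sticky ends (top strand)


# --------------------------------------------------------------------------
# Window enumeration
# --------------------------------------------------------------------------

def scan_target_sites(
    mrna: SeqRecord, constraints: DesignConstraints
) -> list[TargetSite]:
    """Enumerate candidate windows on ``mrna`` passing GC and homopolymer
    filters, sorted by position.

    A window of ``stem_len + loop_len`` nt is taken at every position; it
    is kept when its GC fraction lies in [gc_min, gc_max] and the guide it
    would yield contains no homopolymer run longer than
    ``max_homopolymer``.
    """
    rna = mrna.seq.to_rna()
    w = constraints.window_len
    if len(rna) < w:
        logger.warning(
            "mRNA %s shorter than window (%d < %d); no sites", mrna.id, len(rna), w
        )
        return []
    sites: list[TargetSite] = []
    for start in range(1, len(rna) - w + 2):
        window = NucSeq(rna.residues[start - 1 : start - 1 + w], "RNA")
        gc = window.gc_fraction()
        if not (constraints.gc_min <= gc <= constraints.gc_max):
            continue
        guide = _guide_from_window(window, constraints.first_nt)
        if guide.max_homopolymer() > constraints.max_homopolymer:
            continue
        sites.append(TargetSite(mrna.id, start, window, gc))
    return sites


def _guide_from_window(window: NucSeq, first_nt: str = "A") -> NucSeq:
    # guide position 1 is fixed; positions 2..n complement window[1..n-1]
    tail = NucSeq(window.residues[:-1], "RNA").revcomp()
    return NucSeq(first_nt + tail.residues, "RNA")


def build_guide(site: TargetSite) -> GuideStrand:
    """Derive the guide strand from a target window.

    Position 1 is a fixed A (pairing with the target is not required
    there); positions 2..n are the reverse complement of window[1..n-1].
    """
    guide = _guide_from_window(site.window)
    forced = site.window.residues[-1] != "U"  # A pairs U only
    return GuideStrand(guide, pos1_forced=forced)


# --------------------------------------------------------------------------
# Hairpin builders
# --------------------------------------------------------------------------

def build_hairpin(
    site: TargetSite,
    stem_len: int,
    loop_len: int = 4,
    mismatch_base: str = "C",
) -> HairpinDesign:
    """Generic guide-in-5'-arm hairpin for any stem length 14-24 bp.

    The 5' arm is the first ``stem_len`` nt of the guide, the loop the
    next ``loop_len`` nt (target-complementary), and the 3' arm the
    reverse complement of the 5' arm with its 3'-terminal residue (the
    one opposite guide position 1) replaced by ``mismatch_base`` so that
    the 5' A stays unpaired.
    """
    if not STEM_RANGE[0] <= stem_len <= STEM_RANGE[1]:
        raise DesignError(f"stem_len {stem_len} outside {STEM_RANGE}")
    if mismatch_base not in ("C", "A"):
        raise DesignError("mismatch_base must be C or A")
    if len(site.window) != stem_len + loop_len:
        raise DesignError(
            f"window length {len(site.window)} != stem+loop {stem_len + loop_len}"
        )
    guide = _guide_from_window(site.window)
    arm5 = NucSeq(guide.residues[:stem_len], "RNA")
    loop = NucSeq(guide.residues[stem_len : stem_len + loop_len], "RNA")
    arm3_perfect = arm5.revcomp().residues
    arm3 = NucSeq(arm3_perfect[:-1] + mismatch_base, "RNA")
    mismatches = set()
    if not is_wc_pair(arm5[0], arm3[-1], "RNA"):
        mismatches.add(1)
    return HairpinDesign(
        arm5=arm5,
        loop=loop,
        arm3=arm3,
        guide_arm=GuideArm.FIVE,
        mismatches=frozenset(mismatches),
        stem_len=stem_len,
        loop_len=loop_len,
        site=site,
    )


def build_sairna(
    site: TargetSite,
    stem_len: int = 17,
    loop_len: int = 4,
    mismatch_base: str = "C",
) -> HairpinDesign:
    """Build a saiRNA hairpin (16-18 bp stem, target-complementary loop)."""
    lo, hi = SAIRNA_STEM_RANGE
    if not lo <= stem_len <= hi:
        raise CategoryError(
            f"saiRNA stems are {lo}-{hi} bp; for {stem_len} bp use "
            "build_shrna_5arm (>=21) or build_hairpin"
        )
    return build_hairpin(site, stem_len, loop_len, mismatch_base)


def build_shrna_5arm(
    site: TargetSite,
    stem_len: int = 22,
    loop_len: int = 4,
    mismatch_base: str = "C",
) -> HairpinDesign:
    """Dicer-substrate shRNA with the guide in the 5' arm (21-24 bp stem).

    The same 5'-A and terminal-mismatch rules apply; windows longer than
    the canonical 21-nt target simply extend into the mRNA context
    downstream of it (``scan_target_sites`` already takes the window from
    the transcript, so complementarity holds across the whole span).
    """
    lo, hi = SHRNA_5ARM_STEM_RANGE
    if stem_len < lo:
        raise CategoryError(
            f"5'-arm shRNA stems are {lo}-{hi} bp; shorter stems belong to "
            "build_sairna / build_hairpin"
        )
    if stem_len > hi:
        raise CategoryError(f"5'-arm shRNA stems are {lo}-{hi} bp")
    return build_hairpin(site, stem_len, loop_len, mismatch_base)


def build_shrna_classic(
    site: TargetSite,
    stem_len: int = 21,
    loop_seq: str | NucSeq = TRC_LOOP,
) -> HairpinDesign:
    """Classical shRNA: sense 5' arm, guide in the 3' arm, generic loop.

    The 5' arm copies the first ``stem_len`` nt of the target window, the
    3' arm is its perfect reverse complement (the guide), and the loop is
    a fixed sequence (default: the TRC loop) that is *not*
    target-complementary.
    """
    window = site.window
    if len(window) < stem_len:
        raise DesignError(f"window shorter than stem ({len(window)} < {stem_len})")
    loop = NucSeq(str(loop_seq), "RNA") if not isinstance(loop_seq, NucSeq) else loop_seq
    arm5 = NucSeq(window.residues[:stem_len], "RNA")
    arm3 = arm5.revcomp()
    return HairpinDesign(
        arm5=arm5,
        loop=loop,
        arm3=arm3,
        guide_arm=GuideArm.THREE,
        mismatches=frozenset(),
        stem_len=stem_len,
        loop_len=len(loop),
        site=site,
    )


# --------------------------------------------------------------------------
# Duplex-end asymmetry
# --------------------------------------------------------------------------

#: RNA nearest-neighbour helix-propagation free energies at 37 C
#: (kcal/mol), Watson-Crick stacks (Xia et al. 1998, Turner rules).
#: Keyed by the 5'->3' top-strand dinucleotide of the stack; the partner
#: strand is its exact complement.  Missing keys are looked up via the
#: reverse complement (a stack read from the other strand).
NN_DG37: dict[str, float] = {
    "AA": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08,
    "CA": -2.11,
    "GU": -2.24,
    "GA": -2.35,
    "CG": -2.36,
    "GG": -3.26,
    "GC": -3.42,
}


def nn_stack_dg(dinuc: str) -> float:
    """ΔG°37 of one Watson-Crick stack, symmetric under strand swap."""
    if dinuc in NN_DG37:
        return NN_DG37[dinuc]
    rc = NucSeq(dinuc, "RNA").revcomp().residues
    return NN_DG37[rc]


def _end_dg(design: HairpinDesign, from_five_arm_start: bool, n_bp: int = 4) -> float:
    """Stacking ΔG of the terminal ``n_bp`` window at one duplex end.

    ``from_five_arm_start=True`` measures the end whose 5' strand is the
    start of arm5 (stem positions 1..n); otherwise the opposite end (stem
    positions stem_len-n+1..stem_len read from the arm3 5' side).
    Mismatched positions contribute zero stacking.
    """
    S = design.stem_len
    if from_five_arm_start:
        positions = list(range(1, n_bp + 1))
        strand = design.arm5.residues[:n_bp]
    else:
        positions = list(range(S, S - n_bp, -1))
        strand = design.arm3.residues[:n_bp]
    dg = 0.0
    for k in range(n_bp - 1):
        p, q = positions[k], positions[k + 1]
        if p in design.mismatches or q in design.mismatches:
            continue
        dg += nn_stack_dg(strand[k : k + 2])
    return dg


def asymmetry_score(design: HairpinDesign, n_bp: int = 4) -> float:
    """Duplex-end stability difference, guide end minus passenger end.

    Returns ΔΔG in kcal/mol comparing the unwinding cost of the terminal
    4-bp window at the guide 5' end against the passenger 5' end.
    Negative scores mean the guide 5' end is the less stable one and the
    guide is preferentially retained by the RISC; the score negates
    exactly under a strand swap.
    """
    if design.stem_len < n_bp:
        raise DesignError(f"stem shorter than {n_bp} bp")
    guide_at_arm5 = design.guide_arm is GuideArm.FIVE
    dg_guide_end = _end_dg(design, from_five_arm_start=guide_at_arm5, n_bp=n_bp)
    dg_pass_end = _end_dg(design, from_five_arm_start=not guide_at_arm5, n_bp=n_bp)
    # NN ΔG values are negative for stable stacks: subtracting passenger
    # from guide on the unwinding (positive-stability) scale flips signs.
    return (-dg_guide_end) - (-dg_pass_end)


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------

@dataclass
class RankedDesign:
    design: HairpinDesign
    total: float
    subscores: dict[str, float]


DEFAULT_RANK_WEIGHTS = {"asymmetry": 1.0, "gc": 1.0, "homopolymer": 0.5, "offtarget": 1.0}


def rank_candidates(
    designs: Sequence[HairpinDesign],
    weights: dict[str, float] | None = None,
    offtarget_load: dict[int, float] | None = None,
) -> list[RankedDesign]:
    """Order designs best-first by a weighted sum of per-criterion scores.

    Lower is better for every subscore: the asymmetry ΔΔG, the absolute
    deviation of window GC from 0.5, the guide homopolymer run length,
    and an optional externally supplied off-target load keyed by site
    start.  Ties break toward the 5'-most target position; the sort is
    stable, so the result is invariant to input permutation.
    """
    if not designs:
        raise DesignError("no designs to rank")
    w = dict(DEFAULT_RANK_WEIGHTS)
    if weights:
        w.update(weights)
    logger.info("ranking %d designs with weights %s", len(designs), w)
    ranked = []
    for d in designs:
        sub = {
            "asymmetry": asymmetry_score(d),
            "gc": abs((d.site.gc if d.site else 0.5) - 0.5),
            "homopolymer": float(d.guide.max_homopolymer()),
            "offtarget": float(
                (offtarget_load or {}).get(d.site.start if d.site else -1, 0.0)
            ),
        }
        total = sum(w[k] * v for k, v in sub.items())
        ranked.append(RankedDesign(d, total, sub))
    ranked.sort(key=lambda r: (r.total, r.design.site.start if r.design.site else 0))
    return ranked


# --------------------------------------------------------------------------
# Cloning oligos
# --------------------------------------------------------------------------

# enzyme -> (recognition site, role-specific overhang geometry).  5'
# overhangs contribute a 4-nt single-stranded extension plus the residual
# half-site on the duplex; SphI leaves a 3' overhang (3'-recessed bottom).
_ENZYMES = {
    "BamHI": {"site": "GGATCC", "top_prefix": "GATCC", "bottom_suffix": "G"},
    "HindIII": {"site": "AAGCTT", "top_suffix": "A", "bottom_prefix": "AGCTT"},
    "XbaI": {"site": "TCTAGA", "top_suffix": "T", "bottom_prefix": "CTAGA"},
    "SphI": {"site": "GCATGC", "top_suffix": "GCATG", "bottom_prefix": "C"},
}

VECTORS = {
    "H1_pSilencer": ("BamHI", "HindIII"),
    "lenti_shRNA": ("BamHI", "XbaI"),
    "lenti_saiRNA_RZ": ("BamHI", "SphI"),
}


def make_cloning_oligos(
    construct,
    vector: str = "H1_pSilencer",
    terminator_len: int = 6,
) -> OligoPair:
    """Annealable top/bottom DNA oligos for a named vector.

    ``construct`` is a :class:`HairpinDesign` or any object exposing an
    ``insert_rna()`` method (an expression cassette with spacer and
    ribozyme).  The insert is the hairpin (+spacer+ribozyme if present)
    followed by a poly-T pol III terminator; sticky ends match the
    vector's enzyme pair.  An internal occurrence of either recognition
    site aborts with the offending positions.
    """
    if vector not in VECTORS:
        raise DesignError(f"unknown vector {vector!r}; choose from {sorted(VECTORS)}")
    left, right = VECTORS[vector]
    if hasattr(construct, "insert_rna"):
        body = construct.insert_rna().to_dna().residues
        terminator_len = getattr(construct, "terminator_len", terminator_len)
    else:
        body = construct.core.to_dna().residues
    insert = body + "T" * terminator_len
    for enz in (left, right):
        site = _ENZYMES[enz]["site"]
        hits = _find_all(insert, site)
        if hits:
            raise DesignError(
                f"{enz} site {site} occurs inside the insert at "
                f"position(s) {', '.join(map(str, hits))}"
            )
    e_l, e_r = _ENZYMES[left], _ENZYMES[right]
    top = e_l["top_prefix"] + insert + e_r["top_suffix"]
    bottom = e_r["bottom_prefix"] + NucSeq(insert, "DNA").revcomp().residues + e_l["bottom_suffix"]
    return OligoPair(
        top=NucSeq(top, "DNA"),
        bottom=NucSeq(bottom, "DNA"),
        vector=vector,
        enzymes=(left, right),
        terminator_len=terminator_len,
        insert=NucSeq(insert, "DNA"),
    )


def annealed_insert(pair: OligoPair) -> NucSeq:
    """Reconstruct the cloned insert from an annealed oligo pair.

    Strips the sticky-end extensions and residual half-sites of both
    enzymes from the top oligo; used as the reconstruction oracle.
    """
    e_l, e_r = _ENZYMES[pair.enzymes[0]], _ENZYMES[pair.enzymes[1]]
    top = pair.top.residues
    body = top[len(e_l["top_prefix"]) : len(top) - len(e_r["top_suffix"])]
    # cross-check against the bottom strand
    bottom = pair.bottom.residues
    body_b = bottom[len(e_r["bottom_prefix"]) : len(bottom) - len(e_l["bottom_suffix"])]
    if NucSeq(body_b, "DNA").revcomp().residues != body:
        raise DesignError("top/bottom oligos do not anneal to a consistent insert")
    return NucSeq(body, "DNA")


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i + 1)
        i = haystack.find(needle, i + 1)
    return out
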
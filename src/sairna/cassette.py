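"""Expression-cassette modelling: ribozyme fusion, transcription, scission.

The cassette couples a designed hairpin to a promoter (pol III H1/U6 for
expression in cells, T7 for run-off transcription in vitro), an optional
spacer, a 3' self-cleaving hepatitis delta virus (HDV) ribozyme and a
poly-T pol III terminator.

Pol III termination is leaky at the poly-T signal, so transcripts carry a
3' tail of 4-6 uridines; the ensemble of tail lengths is represented
explicitly with weights rather than sampled.  An active HDV ribozyme
cleaves immediately 5' of its own first nucleotide, independent of the
upstream sequence, leaving a 2',3'-cyclic phosphate on the upstream
product and a 5'-hydroxyl on the downstream (ribozyme + U tail) product.
The C75U point mutation abolishes catalysis.  Cyclic-phosphate ends can
be converted to hydroxyls by T4 PNK (ATP-free); end chemistry is tracked
throughout but does not change downstream loading or stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .designer import HairpinDesign
from .seqcore import EndChemistry, NucSeq

logger = logging.getLogger(__name__)

#: The 84-nt HDV self-cleaving ribozyme commonly fused to run-off
#: transcripts to generate homogeneous 3' ends; catalytic cytosine at
#: position 75.  Fully overridable through :class:`RibozymeSpec`.
HDV_RIBOZYME_SEQ = (
    "GGCCGGCAUGGUCCCAGCCUCCUCGCUGGCGCCGGCUGGGCAACAUUCCGAGGGGACCGUCCCCUCGGUAAUGGCGAAUGGGAC"
)
HDV_CATALYTIC_POS = 75

DEFAULT_SPACER = "UU"  # leaves the short post-cleavage 3' overhang
POL3_TERMINATOR_MIN_T = 5
POL3_U_TAILS = (4, 5, 6)


class CassetteError(ValueError):
    pass


@dataclass(frozen=True)
class RibozymeSpec:
    """An HDV-type self-cleaving ribozyme.

    ``cleavage_offset`` is the number of nucleotides upstream of ribozyme
    nt 1 at which scission occurs (0 = immediately 5' of the ribozyme).
    ``active`` is False iff the catalytic C is mutated to U.
    """

    seq: NucSeq = field(
        default_factory=lambda: NucSeq(HDV_RIBOZYME_SEQ, "RNA")
    )
    cleavage_offset: int = 0
    catalytic_pos: int = HDV_CATALYTIC_POS
    active: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.catalytic_pos <= len(self.seq):
            raise CassetteError("catalytic_pos outside ribozyme sequence")
        res = self.seq[self.catalytic_pos - 1]
        if self.active and res != "C":
            raise CassetteError(
                f"active ribozyme requires C at position {self.catalytic_pos}, "
                f"found {res}"
            )

    @classmethod
    def wild_type(cls) -> "RibozymeSpec":
        return cls()

    @classmethod
    def c75u(cls) -> "RibozymeSpec":
        """Catalytically dead point mutant (C->U at the catalytic site)."""
        wt = HDV_RIBOZYME_SEQ
        p = HDV_CATALYTIC_POS
        mutated = wt[: p - 1] + "U" + wt[p:]
        return cls(seq=NucSeq(mutated, "RNA"), catalytic_pos=p, active=False)


@dataclass
class ExpressionCassette:
    promoter: str  # H1 | U6 | T7
    hairpin: HairpinDesign
    spacer: NucSeq | None = None
    ribozyme: RibozymeSpec | None = None
    terminator_len: int = 6

    def __post_init__(self) -> None:
        if self.promoter not in ("H1", "U6", "T7"):
            raise CassetteError(f"unknown promoter {self.promoter!r}")
        if self.promoter in ("H1", "U6") and self.terminator_len < POL3_TERMINATOR_MIN_T:
            raise CassetteError(
                f"pol III cassette needs a >= {POL3_TERMINATOR_MIN_T}-T terminator"
            )

    def insert_rna(self) -> NucSeq:
        """Templated insert as RNA: hairpin core [+ spacer + ribozyme]."""
        s = self.hairpin.core.residues
        if self.spacer is not None:
            s += self.spacer.to_rna().residues
        if self.ribozyme is not None:
            s += self.ribozyme.seq.to_rna().residues
        return NucSeq(s, "RNA")


@dataclass
class Transcript:
    seq: NucSeq  # RNA
    ends: EndChemistry
    u_tail_len: int = 0
    weight: float = 1.0

    def __post_init__(self) -> None:
        run = 0
        for ch in reversed(self.seq.residues):
            if ch == "U":
                run += 1
            else:
                break
        if self.u_tail_len > run:
            raise CassetteError(
                f"u_tail_len {self.u_tail_len} exceeds terminal U run {run}"
            )


@dataclass
class CleavageResult:
    occurred: bool
    upstream: Transcript
    downstream: Transcript | None = None


def attach_ribozyme(
    design: HairpinDesign,
    variant: str = "WT",
    spacer: str | NucSeq = DEFAULT_SPACER,
    promoter: str = "H1",
    terminator_len: int = 6,
) -> ExpressionCassette:
    """Fuse an HDV ribozyme (or none) downstream of the hairpin 3' arm.

    Scission leaves exactly ``len(spacer)`` nt beyond the 3' arm, so the
    spacer sets the post-cleavage 3' overhang.  A spacer containing >=4 U
    would act as a premature pol III terminator and is rejected.
    """
    sp = NucSeq(str(spacer), "RNA").to_rna() if spacer else None
    if sp is not None and sp.max_homopolymer("U") >= 4:
        raise CassetteError("spacer contains >=4 U: collides with the pol III terminator")
    v = variant.upper()
    if v in ("WT", "WILD_TYPE"):
        rz = RibozymeSpec.wild_type()
    elif v in ("C75U", "MUT", "MRZ"):
        rz = RibozymeSpec.c75u()
    elif v in ("NONE", ""):
        rz = None
        sp = None  # a bare design carries no spacer remnant
    else:
        raise CassetteError(f"unknown ribozyme variant {variant!r}")
    return ExpressionCassette(
        promoter=promoter,
        hairpin=design,
        spacer=sp,
        ribozyme=rz,
        terminator_len=terminator_len,
    )


def transcribe_pol3(
    cassette: ExpressionCassette,
    tail_weights: dict[int, float] | None = None,
) -> list[Transcript]:
    """Pol III transcript ensemble: insert + 4/5/6-U tail, 5' PPP.

    Tail-length weights default to uniform over 4-6 U and are normalized;
    the ensemble is deterministic (weighted), never sampled.
    """
    if cassette.promoter not in ("H1", "U6"):
        raise CassetteError("transcribe_pol3 requires an H1 or U6 promoter")
    if cassette.terminator_len < POL3_TERMINATOR_MIN_T:
        raise CassetteError("missing pol III terminator")
    insert = cassette.insert_rna()
    first = insert[0]
    if cassette.promoter == "H1" and first != "A":
        logger.warning("H1 transcripts initiate best on A; insert starts with %s", first)
    if cassette.promoter == "U6" and first != "G":
        logger.warning("U6 transcripts initiate best on G; insert starts with %s", first)
    weights = dict(tail_weights) if tail_weights else {n: 1.0 for n in POL3_U_TAILS}
    total = sum(weights.values())
    if total <= 0:
        raise CassetteError("tail weights must sum to a positive value")
    out = []
    for n, w in sorted(weights.items()):
        out.append(
            Transcript(
                seq=NucSeq(insert.residues + "U" * n, "RNA"),
                ends=EndChemistry("PPP", "OH"),
                u_tail_len=n,
                weight=w / total,
            )
        )
    return out


def transcribe_t7(cassette: ExpressionCassette) -> Transcript:
    """Run-off T7 transcript: the full templated insert, 5' PPP, no tail."""
    if cassette.promoter != "T7":
        raise CassetteError("transcribe_t7 requires the T7 promoter")
    return Transcript(
        seq=cassette.insert_rna(), ends=EndChemistry("PPP", "OH"), u_tail_len=0
    )


def ribozyme_cleave(t: Transcript, rz: RibozymeSpec) -> CleavageResult:
    """Self-scission at the ribozyme's 5' boundary.

    Active ribozyme: the upstream product ends ``cleavage_offset`` nt
    before ribozyme nt 1 with a 2',3'-cyclic phosphate; the downstream
    product (ribozyme + any tail) starts with a 5'-OH.  Inactive (C75U)
    ribozyme: no scission, the input is returned intact.  The cut site
    depends only on the ribozyme's own position, never on the upstream
    sequence.
    """
    rz_rna = rz.seq.to_rna().residues
    idx = t.seq.residues.rfind(rz_rna)
    if idx == -1:
        raise CassetteError("ribozyme sequence not found in transcript")
    if not rz.active:
        return CleavageResult(occurred=False, upstream=t, downstream=None)
    cut = idx - rz.cleavage_offset
    if cut <= 0:
        raise CassetteError("cleavage point falls at or before the transcript 5' end")
    upstream = Transcript(
        seq=NucSeq(t.seq.residues[:cut], "RNA"),
        ends=EndChemistry(t.ends.five_prime, "CyclicP"),
        u_tail_len=0,
        weight=t.weight,
    )
    downstream = Transcript(
        seq=NucSeq(t.seq.residues[cut:], "RNA"),
        ends=EndChemistry("OH", t.ends.three_prime),
        u_tail_len=t.u_tail_len,
        weight=t.weight,
    )
    return CleavageResult(occurred=True, upstream=upstream, downstream=downstream)


def pnk_dephosphorylate(t: Transcript) -> Transcript:
    """T4 PNK (ATP-free) converts a 2',3'-cyclic phosphate to 3'-OH."""
    if t.ends.three_prime != "CyclicP":
        logger.warning("3' end is already %s; PNK treatment is a no-op", t.ends.three_prime)
        return t
    return replace(t, ends=EndChemistry(t.ends.five_prime, "OH"))


def t7_fusion_from_oligos(oligos_fasta) -> Transcript | None:
    """Reconstruct a hairpin-ribozyme fusion transcript from published
    template oligos.

    ``oligos_fasta`` is a user-supplied FASTA holding the top-strand DNA
    template of a saiRNA-ribozyme fusion (a single record, or several
    records concatenated in order).  Returns the run-off T7 transcript,
    or None with a warning when the file is absent — the reference
    construct sequences are distributed in a publication's supplementary
    material and are not bundled here.
    """
    from pathlib import Path

    from .seqcore import read_fasta

    path = Path(oligos_fasta)
    if not path.exists():
        logger.warning(
            "supplementary oligo file %s not found; skipping fusion reconstruction",
            path,
        )
        return None
    records = read_fasta(path, alphabet="DNA")
    template = "".join(r.seq.residues for r in records)
    return Transcript(
        seq=NucSeq(template, "DNA").to_rna(),
        ends=EndChemistry("PPP", "OH"),
        u_tail_len=0,
    )


@dataclass
class FoldedPrecursor:
    """The hairpin transcript after template-directed folding.

    Pairing follows the design (the stem is known, not predicted):
    ``stem_pairs`` are 1-based transcript coordinates, overhangs are the
    unpaired terminal runs (3' overhang = spacer remnant and/or U tail).
    """

    stem_pairs: frozenset[tuple[int, int]]
    loop_span: tuple[int, int]
    overhang5: int
    overhang3: int
    source: Transcript
    design: HairpinDesign

    @property
    def stem_len(self) -> int:
        return self.design.stem_len


def fold_hairpin(t: Transcript, design: HairpinDesign) -> FoldedPrecursor:
    """Fold a transcript onto its design and measure the overhangs."""
    core = design.core.residues
    idx = t.seq.residues.find(core)
    if idx == -1:
        raise CassetteError("transcript does not contain the designed hairpin core")
    S, L = design.stem_len, design.loop_len
    pairs = set()
    for i in range(1, S + 1):
        if i in design.mismatches:
            continue
        pairs.add((idx + i, idx + 2 * S + L + 1 - i))
    return FoldedPrecursor(
        stem_pairs=frozenset(pairs),
        loop_span=(idx + S + 1, idx + S + L),
        overhang5=idx,
        overhang3=len(t.seq) - idx - len(core),
        source=t,
        design=design,
    )
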
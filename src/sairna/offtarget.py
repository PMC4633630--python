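"""Seed-mediated off-target analysis and synthetic-transcriptome fixtures.

Off-target repression of unintended mRNAs is driven miRNA-like by the
siRNA *seed* (strand positions 2-7): a 3' UTR containing the exact
reverse complement of the seed hexamer is a candidate off-target.  Both
the guide and, for Dicer-made duplexes, the passenger strand contribute
seeds; saiRNA eliminates the passenger, so its passenger-seed exposure
is structurally zero.

The differential-expression attribution mirrors a standard transcriptome
screen: genes expressed above an FPKM floor are classified up/down by a
fold-change cutoff against a control sample, and downregulated genes are
intersected with seed-site presence per strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designer import GuideArm, HairpinDesign
from .processing import Category, ProcessingOutcome
from .seqcore import NucSeq, SeqRecord

logger = logging.getLogger(__name__)

SEED_SPAN = (2, 7)  # 1-based inclusive positions on the small-RNA strand


class OfftargetError(ValueError):
    pass


@dataclass(frozen=True)
class Seed:
    hexamer: NucSeq
    origin: str  # GUIDE | PASSENGER

    def __post_init__(self) -> None:
        if len(self.hexamer) != 6:
            raise OfftargetError("seed must be exactly 6 nt")

    @property
    def match_site(self) -> str:
        """The UTR motif a seed pairs: the reverse complement hexamer."""
        return self.hexamer.revcomp().residues


def extract_seed(strand: NucSeq, origin: str = "GUIDE") -> Seed:
    """Seed = strand positions 2-7 (1-based from the 5' end)."""
    if len(strand) < SEED_SPAN[1]:
        raise OfftargetError(
            f"strand of {len(strand)} nt is too short for a position-2-7 seed"
        )
    return Seed(NucSeq(strand.residues[SEED_SPAN[0] - 1 : SEED_SPAN[1]], strand.alphabet), origin)


def major_isoform_seed(outcome: ProcessingOutcome, origin: str = "GUIDE") -> Seed | None:
    """Seed of the highest-weight mature isoform of the requested strand.

    Returns None when the strand species does not exist (e.g. passenger
    for any saiRNA outcome).
    """
    name = "mature_guide" if origin == "GUIDE" else "siRNA_passenger"
    if origin == "GUIDE":
        candidates = [s for s in outcome.species if s.name in ("mature_guide", "siRNA_guide")]
    else:
        candidates = [s for s in outcome.species if s.name == "siRNA_passenger"]
    if not candidates:
        return None
    best = max(candidates, key=lambda s: s.weight)
    return extract_seed(best.seq, origin)


@dataclass
class SeedMatchReport:
    seed: Seed
    per_utr: pd.DataFrame  # columns: utr_id, n_sites, positions
    genes_with_site: int
    total_sites: int


def scan_seed_matches(seed: Seed, utrs: list[SeqRecord]) -> SeedMatchReport:
    """Count exact reverse-complement seed sites per UTR.

    Overlapping occurrences are counted; matching is alphabet-agnostic
    (UTRs may be DNA or RNA).
    """
    motif_rna = NucSeq(seed.match_site, seed.hexamer.alphabet).to_rna().residues
    rows = []
    for rec in utrs:
        hay = rec.seq.to_rna().residues
        positions = _find_all_overlapping(hay, motif_rna)
        rows.append({"utr_id": rec.id, "n_sites": len(positions), "positions": positions})
    df = pd.DataFrame(rows, columns=["utr_id", "n_sites", "positions"])
    return SeedMatchReport(
        seed=seed,
        per_utr=df,
        genes_with_site=int((df["n_sites"] > 0).sum()) if len(df) else 0,
        total_sites=int(df["n_sites"].sum()) if len(df) else 0,
    )


def _find_all_overlapping(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i + 1)  # 1-based
        i = haystack.find(needle, i + 1)
    return out


@dataclass
class ExpressionTable:
    """Per-gene FPKM in control and treated samples."""

    table: pd.DataFrame  # columns: gene_id, fpkm_control, fpkm_treated

    def __post_init__(self) -> None:
        req = {"gene_id", "fpkm_control", "fpkm_treated"}
        if not req.issubset(self.table.columns):
            raise OfftargetError(f"expression table needs columns {sorted(req)}")
        if (self.table[["fpkm_control", "fpkm_treated"]] < 0).any().any():
            raise OfftargetError("FPKM values must be >= 0")


@dataclass
class AttributionTable:
    """Counts mirroring a differential-expression attribution summary.

    ``passenger_seed_down`` is None ("NA") when the construct produces no
    passenger strand (every saiRNA).
    """

    upregulated: int
    downregulated: int
    guide_seed_down: int
    passenger_seed_down: int | None
    genes_without_utr: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "upregulated": self.upregulated,
                "downregulated": self.downregulated,
                "guide_seed_down": self.guide_seed_down,
                "passenger_seed_down": (
                    "NA" if self.passenger_seed_down is None else self.passenger_seed_down
                ),
            }
        )


def attribute_deg(
    expr: ExpressionTable,
    guide_seed: Seed | None,
    passenger_seed: Seed | None,
    utrs: list[SeqRecord],
    fpkm_min: float = 10.0,
    fc: float = 1.5,
    pseudocount: float = 0.0,
) -> AttributionTable:
    """Classify expressed genes by fold change and attribute downregulation
    to seed-site presence per strand.

    Genes with control FPKM >= ``fpkm_min`` are kept; treated/control
    ratios >= ``fc`` (or <= 1/``fc``) count as up-/downregulated, ties at
    the threshold included.  Guide and passenger attributions are
    independent (a gene may carry both site types).  Genes lacking a UTR
    record are counted in up/down but excluded from seed attribution.
    """
    df = expr.table
    kept = df[df["fpkm_control"] >= fpkm_min].copy()
    ratio = (kept["fpkm_treated"] + pseudocount) / (kept["fpkm_control"] + pseudocount)
    up = kept[ratio >= fc]
    down = kept[ratio <= 1.0 / fc]
    utr_by_id = {r.id: r for r in utrs}
    down_ids = list(down["gene_id"])
    missing = [g for g in down_ids if g not in utr_by_id]
    if missing:
        logger.info("%d downregulated genes lack UTR records", len(missing))

    def n_with_site(seed: Seed | None) -> int | None:
        if seed is None:
            return None
        motif = NucSeq(seed.match_site, seed.hexamer.alphabet).to_rna().residues
        n = 0
        for g in down_ids:
            rec = utr_by_id.get(g)
            if rec is not None and motif in rec.seq.to_rna().residues:
                n += 1
        return n

    return AttributionTable(
        upregulated=len(up),
        downregulated=len(down),
        guide_seed_down=n_with_site(guide_seed) or 0,
        passenger_seed_down=n_with_site(passenger_seed),
        genes_without_utr=len(missing),
    )


# --------------------------------------------------------------------------
# Antisense-transcript risk
# --------------------------------------------------------------------------

def antisense_risk(
    outcome: ProcessingOutcome, antisense_transcripts: list[SeqRecord]
) -> pd.DataFrame:
    """Flag antisense transcripts cleavable by a surviving passenger strand.

    A Dicer-made passenger strand is sense to the target mRNA, hence
    perfectly complementary to its antisense transcript; any transcript
    carrying a perfect >=21-nt match site is flagged ``PERFECT_MATCH``.
    saiRNA outcomes have no passenger, so the report carries no risk.
    """
    rows = []
    passengers = [s.seq for s in outcome.species if s.name == "siRNA_passenger"]
    for rec in antisense_transcripts:
        hay = rec.seq.to_rna().residues
        flag = "NONE"
        for p in passengers:
            site = p.to_rna().revcomp().residues[:21] if len(p) >= 21 else None
            if site and site in hay:
                flag = "PERFECT_MATCH"
                break
        rows.append({"transcript_id": rec.id, "risk": flag})
    return pd.DataFrame(rows, columns=["transcript_id", "risk"])


# --------------------------------------------------------------------------
# Synthetic transcriptome
# --------------------------------------------------------------------------

@dataclass
class PlantedEffect:
    gene_id: str
    seed_origin: str | None  # GUIDE | PASSENGER | None (seed-free change)
    fold_change: float  # >1: planted downregulation by this factor
    n_sites: int = 1


@dataclass
class SyntheticTranscriptome:
    utrs: list[SeqRecord]
    expression: ExpressionTable
    planted: list[PlantedEffect]
    rng_seed: int


def synth_transcriptome(
    n_genes: int,
    guide_seed: Seed,
    passenger_seed: Seed | None = None,
    utr_len_range: tuple[int, int] = (200, 1200),
    n_guide_targets: int = 20,
    n_passenger_targets: int = 0,
    fold_change: float = 2.0,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
    fpkm_min: float = 10.0,
    background_motif_free: bool = True,
    n_background_down: int = 0,
    rng_seed: int = 0,
    max_tries: int = 200,
) -> SyntheticTranscriptome:
    """Generate UTRs and an expression table with planted seed effects.

    Background UTRs are rejection-sampled so they contain *no* match site
    for either seed; target genes then receive ``fold_change``-fold
    downregulation and exactly the requested number of planted sites for
    their strand's seed, so a noise-free attribution recovers the planted
    truth exactly.  Baseline FPKM is log-normal, floored at ``fpkm_min``
    so every gene survives the expression filter.  Regeneration with the
    same seed is byte-identical.

    Noise modes: ``background_motif_free=False`` leaves chance seed sites
    in background UTRs, and ``n_background_down`` downregulates that many
    non-planted genes (seed-independent changes).  Background genes that
    are downregulated *and* happen to carry a seed site are collisions;
    their count is logged so recovery tests can account for them.
    """
    if n_genes < 0 or n_guide_targets < 0 or n_passenger_targets < 0:
        raise OfftargetError("counts must be non-negative")
    if n_guide_targets + n_passenger_targets > n_genes:
        raise OfftargetError("more planted targets than genes")
    if fold_change <= 1.0:
        raise OfftargetError("fold_change must exceed 1")
    if passenger_seed is None and n_passenger_targets > 0:
        raise OfftargetError("passenger targets requested without a passenger seed")
    rng = np.random.default_rng(rng_seed)
    motifs = [guide_seed.match_site.replace("T", "U")]
    if passenger_seed is not None:
        motifs.append(passenger_seed.match_site.replace("T", "U"))

    utrs: list[SeqRecord] = []
    for gi in range(n_genes):
        length = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        if length < 30:
            raise OfftargetError("UTRs shorter than 30 nt are not supported")
        for _ in range(max_tries):
            seq = "".join(rng.choice(list("ACGU"), size=length))
            if not background_motif_free or not any(m in seq for m in motifs):
                break
        else:
            raise OfftargetError(
                "could not sample a motif-free background UTR; shorten UTRs"
            )
        utrs.append(SeqRecord(f"gene{gi:04d}", NucSeq(seq, "RNA")))

    planted: list[PlantedEffect] = []
    order = rng.permutation(n_genes)
    guide_idx = order[:n_guide_targets]
    pass_idx = order[n_guide_targets : n_guide_targets + n_passenger_targets]
    for idxs, origin, motif in (
        (guide_idx, "GUIDE", motifs[0]),
        (pass_idx, "PASSENGER", motifs[1] if passenger_seed else None),
    ):
        other = [m for m in motifs if m != motif]
        for gi in idxs:
            rec = utrs[gi]
            n_sites = int(rng.integers(1, 4))
            for _ in range(max_tries):
                seq = rec.seq.residues
                for _ in range(n_sites):
                    pos = int(rng.integers(0, len(seq) - 6))
                    seq = seq[:pos] + motif + seq[pos + 6 :]
                # planting may clobber a previous site or create a junction
                # motif for the other strand; re-sample until clean
                if not any(m in seq for m in other):
                    break
            else:
                raise OfftargetError("could not plant sites without cross-motif collisions")
            actual = seq.count(motif)
            utrs[gi] = SeqRecord(rec.id, NucSeq(seq, "RNA"))
            planted.append(
                PlantedEffect(rec.id, origin, fold_change, n_sites=actual)
            )

    baseline = np.maximum(
        np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes)), fpkm_min
    )
    treated = baseline.copy()
    for eff in planted:
        gi = int(eff.gene_id[4:])
        treated[gi] = baseline[gi] / eff.fold_change
    # seed-independent background downregulation (noise mode)
    background_pool = order[n_guide_targets + n_passenger_targets :]
    if n_background_down > len(background_pool):
        raise OfftargetError("n_background_down exceeds the non-planted gene pool")
    collisions = 0
    for gi in background_pool[:n_background_down]:
        treated[gi] = baseline[gi] / fold_change
        if any(m in utrs[gi].seq.residues for m in motifs):
            collisions += 1
    if n_background_down:
        logger.info(
            "background downregulation: %d genes, %d seed-site collisions",
            n_background_down,
            collisions,
        )
    expr = ExpressionTable(
        pd.DataFrame(
            {
                "gene_id": [u.id for u in utrs],
                "fpkm_control": baseline,
                "fpkm_treated": treated,
            }
        )
    )
    return SyntheticTranscriptome(
        utrs=utrs, expression=expr, planted=planted, rng_seed=rng_seed
    )
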
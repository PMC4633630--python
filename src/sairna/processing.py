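"""Processing simulation: Dicer vs Ago2 maturation and Ago partitioning.

Hairpin precursors fall into stem-length categories with sharply
different fates:

* ``DICER`` (stem >= 21 bp): diced into 21-24-nt siRNA duplexes with
  2-nt 3' overhangs; both strands are potential RISC cargo.
* ``AGO2_SAI`` (16-18 bp): loaded by Ago2 when the 3' overhang is short,
  sliced across the 3' arm opposite guide positions 10/11, and the
  retained 5' product is 3'-trimmed into mature single-stranded guides
  (21-24 nt).  No passenger strand survives.
* ``DEAD_ZONE`` (19-20 bp): sliced by Ago2 but the intermediate (>30 nt)
  is too stable to unwind and trim; no mature siRNA is produced.
* ``SUBOPTIMAL`` (< 16 bp): bound but yields no product.

Ago2 loading is gated by the precursor 3'-overhang length (a ~2-nt
overhang loads fully; a pol III 4-6-U tail does not load at all).  Only
Ago2 is slicer-competent, so saiRNA-derived mature guides partition to
Ago2 exclusively, while Dicer-made duplexes distribute across Ago1-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .cassette import (
    ExpressionCassette,
    FoldedPrecursor,
    attach_ribozyme,
    fold_hairpin,
    ribozyme_cleave,
    transcribe_pol3,
)
from .designer import GuideArm, HairpinDesign
from .seqcore import NucSeq

logger = logging.getLogger(__name__)

AGOS = ("Ago1", "Ago2", "Ago3", "Ago4")
SPECIES_COLS = ("precursor", "intermediate", "mature_guide", "mature_passenger")

#: Guide positions flanking the slice bond on the 3' arm (canonical Ago2
#: slicer register: the 3' strand is cut between the residues paired to
#: guide positions 11 and 10).
SLICE_GUIDE_POSITIONS = (10, 11)

DICER_MIN_STEM = 21
SAI_STEM = (16, 18)
DEAD_ZONE_STEM = (19, 20)

DEFAULT_DICER_LEN_WEIGHTS = {21: 0.4, 22: 0.4, 23: 0.1, 24: 0.1}
MATURE_LEN_RANGE = (21, 24)


class Category(str, Enum):
    DICER = "DICER"
    AGO2_SAI = "AGO2_SAI"
    DEAD_ZONE = "DEAD_ZONE"
    SUBOPTIMAL = "SUBOPTIMAL"


class ProcessingError(ValueError):
    pass


class CategoryError(ProcessingError):
    """An operation was applied to a precursor of the wrong category."""


def classify_precursor(p: FoldedPrecursor | int) -> Category:
    """Stem-length category; accepts a precursor or a bare stem length."""
    stem = p if isinstance(p, int) else p.stem_len
    if stem >= DICER_MIN_STEM:
        return Category.DICER
    if DEAD_ZONE_STEM[0] <= stem <= DEAD_ZONE_STEM[1]:
        return Category.DEAD_ZONE
    if SAI_STEM[0] <= stem <= SAI_STEM[1]:
        return Category.AGO2_SAI
    return Category.SUBOPTIMAL


@dataclass(frozen=True)
class SiRNADuplex:
    guide: NucSeq
    passenger: NucSeq
    overhang3_guide: int
    overhang3_passenger: int
    weight: float


@dataclass
class Ago2Outcome:
    category: Category
    slice_bond: tuple[int, int]  # guide positions flanking the cut
    intermediate: NucSeq
    released3: NucSeq  # the 3' fragment cut away (for conservation checks)
    matures: list[tuple[NucSeq, float]]
    passenger_species: list  # structurally empty: Ago2 slicing destroys it


@dataclass(frozen=True)
class LoadingDecision:
    overhang3: int
    ago2_load_weight: float


@dataclass
class GateThresholds:
    """Ago2-loading step function over the precursor 3'-overhang length."""

    full_max: int = 2  # overhang <= 2 nt: full loading
    half_at: int = 3  # 3 nt: half
    # >= half_at + 1: no loading


def ago2_load(p: FoldedPrecursor, gate: GateThresholds | None = None) -> LoadingDecision:
    """Overhang-gated Ago2 loading weight (monotone non-increasing)."""
    g = gate or GateThresholds()
    oh = p.overhang3
    if oh <= g.full_max:
        w = 1.0
    elif oh == g.half_at:
        w = 0.5
    else:
        w = 0.0
    return LoadingDecision(overhang3=oh, ago2_load_weight=w)


def dicer_process(
    p: FoldedPrecursor,
    length_weights: dict[int, float] | None = None,
) -> list[SiRNADuplex]:
    """Dice a long-stem precursor into weighted 21-24-nt siRNA duplexes.

    Strand lengths follow ``length_weights`` (default concentrated at
    21-22 nt) clipped to what the stem can provide; every duplex carries
    2-nt 3' overhangs and both strands are reported.
    """
    if classify_precursor(p) is not Category.DICER:
        raise CategoryError(f"dicer_process requires a DICER precursor, got stem {p.stem_len}")
    d = p.design
    core = d.core.residues
    weights = dict(length_weights or DEFAULT_DICER_LEN_WEIGHTS)
    feasible = {
        n: w
        for n, w in weights.items()
        if MATURE_LEN_RANGE[0] <= n <= min(MATURE_LEN_RANGE[1], d.stem_len + 2)
    }
    if not feasible:
        raise ProcessingError("no feasible Dicer product length")
    total = sum(feasible.values())
    out = []
    for n in sorted(feasible):
        strand5 = NucSeq(core[:n], "RNA")
        strand3 = NucSeq(core[-n:], "RNA")
        guide, passenger = (
            (strand5, strand3) if d.guide_arm is GuideArm.FIVE else (strand3, strand5)
        )
        out.append(
            SiRNADuplex(
                guide=guide,
                passenger=passenger,
                overhang3_guide=2,
                overhang3_passenger=2,
                weight=feasible[n] / total,
            )
        )
    return out


def ago2_process(
    p: FoldedPrecursor,
    mature_length_weights: dict[int, float] | None = None,
) -> Ago2Outcome:
    """Ago2 slicing of the 3' arm and (for saiRNA) 3'->5' trimming.

    The 3' strand is cut between the residues paired to guide positions
    11 and 10, so the retained 5' product has length
    ``stem + loop + (stem - 10)`` plus any 5' overhang.  For 16-18-bp
    stems the intermediate is trimmed to mature single-stranded guides of
    21..min(24, intermediate) nt sharing the precursor 5' end; for
    19-20-bp stems the intermediate is emitted as-is with no matures.
    Passenger species are structurally absent in both cases.
    """
    cat = classify_precursor(p)
    if cat is Category.DICER:
        raise CategoryError("ago2_process cannot act on a DICER (>=21 bp) precursor")
    if cat is Category.SUBOPTIMAL:
        raise CategoryError("ago2_process requires a 16-20 bp stem")
    d = p.design
    S, L = d.stem_len, d.loop_len
    seq = p.source.seq.residues
    cut = p.overhang5 + 2 * S + L - SLICE_GUIDE_POSITIONS[0]
    intermediate = NucSeq(seq[:cut], "RNA")
    released = NucSeq(seq[cut:], "RNA")
    matures: list[tuple[NucSeq, float]] = []
    if cat is Category.AGO2_SAI:
        lo, hi = MATURE_LEN_RANGE
        hi = min(hi, len(intermediate))
        weights = mature_length_weights or {n: 1.0 for n in range(lo, hi + 1)}
        feas = {n: w for n, w in weights.items() if lo <= n <= hi}
        total = sum(feas.values())
        for n in sorted(feas):
            matures.append((NucSeq(intermediate.residues[:n], "RNA"), feas[n] / total))
    return Ago2Outcome(
        category=cat,
        slice_bond=SLICE_GUIDE_POSITIONS,
        intermediate=intermediate,
        released3=released,
        matures=matures,
        passenger_species=[],
    )


# --------------------------------------------------------------------------
# Ago partitioning
# --------------------------------------------------------------------------

def ago_partition(
    p: FoldedPrecursor,
    outcome,
    ago3_residual: float = 0.0,
    ago4_weight: float = 1.0,
    ago2_knockout: bool = False,
) -> pd.DataFrame:
    """Association weights of Ago1-4 with each RNA species.

    Dicer duplexes load guide and passenger into all four Agos with equal
    default weights (``ago4_weight`` lowers Ago4, which is often below
    detection).  Ago2-route outcomes put intermediate and mature guide on
    Ago2 only; the non-nucleolytic Agos bind the unprocessed precursor.
    ``ago3_residual`` optionally grants Ago3 a small mature weight
    (residual slicer activity).  ``ago2_knockout`` zeroes the Ago2 row.
    """
    table = pd.DataFrame(0.0, index=list(AGOS), columns=list(SPECIES_COLS))
    if isinstance(outcome, list) and all(isinstance(x, SiRNADuplex) for x in outcome):
        for ago in AGOS:
            w = ago4_weight if ago == "Ago4" else 1.0
            table.loc[ago, "mature_guide"] = w
            table.loc[ago, "mature_passenger"] = w
    elif isinstance(outcome, Ago2Outcome):
        gate = ago2_load(p).ago2_load_weight
        table.loc["Ago2", "precursor"] = gate
        table.loc["Ago2", "intermediate"] = 1.0
        if outcome.matures:
            table.loc["Ago2", "mature_guide"] = 1.0
            table.loc["Ago3", "mature_guide"] = ago3_residual
        table.loc["Ago1", "precursor"] = 1.0
        table.loc["Ago3", "precursor"] = 1.0
        table.loc["Ago4", "precursor"] = 1.0 * ago4_weight
    else:
        raise ProcessingError("outcome must be Dicer duplexes or an Ago2Outcome")
    if ago2_knockout:
        table.loc["Ago2"] = 0.0
    return table


# --------------------------------------------------------------------------
# End-to-end simulation
# --------------------------------------------------------------------------

@dataclass
class SimOptions:
    promoter: str = "H1"
    ribozyme: str = "WT"  # WT | C75U | NONE
    spacer: str = "UU"
    terminator_len: int = 6
    tail_weights: dict[int, float] | None = None
    gate: GateThresholds = field(default_factory=GateThresholds)
    dicer_length_weights: dict[int, float] | None = None
    mature_length_weights: dict[int, float] | None = None
    ago3_residual: float = 0.0
    ago4_weight: float = 1.0
    ago2_knockout: bool = False
    #: fraction of an un-loadable (long-overhang) precursor that appears
    #: as a minor 3'-trimmed short isoform and becomes loadable anyway
    trim_leak: float = 0.05


@dataclass
class SpeciesRecord:
    name: str  # precursor | intermediate | mature_guide | siRNA_guide | siRNA_passenger
    seq: NucSeq
    weight: float


@dataclass
class ProcessingOutcome:
    design: HairpinDesign
    category: Category
    species: list[SpeciesRecord]
    ago_table: pd.DataFrame
    loading: LoadingDecision
    diagnostics: dict

    def species_weights(self) -> dict[str, float]:
        agg: dict[str, float] = {}
        for s in self.species:
            agg[s.name] = agg.get(s.name, 0.0) + s.weight
        return agg


def simulate(design: HairpinDesign, options: SimOptions | None = None) -> ProcessingOutcome:
    """Full deterministic pipeline for one design.

    Transcription (pol III ensemble) -> optional ribozyme self-cleavage
    -> folding -> stem-length classification -> Dicer or Ago2 processing
    weighted by the overhang gate -> Ago partition table.  All weights
    are ensemble-propagated; nothing is sampled.
    """
    opt = options or SimOptions()
    cassette = attach_ribozyme(
        design,
        variant=opt.ribozyme,
        spacer=opt.spacer,
        promoter=opt.promoter,
        terminator_len=opt.terminator_len,
    )
    transcripts = transcribe_pol3(cassette, tail_weights=opt.tail_weights)

    precursors: list[FoldedPrecursor] = []
    for t in transcripts:
        if cassette.ribozyme is not None:
            res = ribozyme_cleave(t, cassette.ribozyme)
            precursors.append(fold_hairpin(res.upstream, design))
        else:
            precursors.append(fold_hairpin(t, design))

    category = classify_precursor(precursors[0])
    species: list[SpeciesRecord] = []
    diagnostics: dict = {
        "ribozyme": opt.ribozyme,
        "dicer_and_ago2_bound": category is Category.DEAD_ZONE,
    }
    agg_gate = 0.0
    outcome_for_partition = None

    for p in precursors:
        w = p.source.weight
        gate = ago2_load(p, opt.gate).ago2_load_weight
        if category is Category.DICER:
            duplexes = dicer_process(p, opt.dicer_length_weights)
            for dx in duplexes:
                species.append(SpeciesRecord("siRNA_guide", dx.guide, w * dx.weight))
                species.append(
                    SpeciesRecord("siRNA_passenger", dx.passenger, w * dx.weight)
                )
            outcome_for_partition = duplexes
            agg_gate += w * gate
            continue
        # Ago2 route: the gate decides how much precursor is processed;
        # a small trim leak lets a long-overhang precursor in slowly.
        eff = gate if gate > 0 else opt.trim_leak
        eff = 0.0 if opt.ago2_knockout else eff
        agg_gate += w * gate
        unprocessed = w * (1.0 - eff)
        if unprocessed > 0:
            species.append(SpeciesRecord("precursor", p.source.seq, unprocessed))
        if eff > 0 and category in (Category.AGO2_SAI, Category.DEAD_ZONE):
            out = ago2_process(p, opt.mature_length_weights)
            if category is Category.DEAD_ZONE or not out.matures:
                species.append(
                    SpeciesRecord("intermediate", out.intermediate, w * eff)
                )
            else:
                # steady state: intermediates are mostly consumed into
                # matures; keep a visible intermediate pool alongside
                inter_frac = 0.2
                species.append(
                    SpeciesRecord("intermediate", out.intermediate, w * eff * inter_frac)
                )
                for seq, mw in out.matures:
                    species.append(
                        SpeciesRecord(
                            "mature_guide", seq, w * eff * (1 - inter_frac) * mw
                        )
                    )
            outcome_for_partition = out
        elif eff > 0:  # SUBOPTIMAL: bound but no product
            species.append(SpeciesRecord("precursor", p.source.seq, w * eff))

    loading = LoadingDecision(
        overhang3=precursors[0].overhang3, ago2_load_weight=agg_gate
    )
    if outcome_for_partition is None:
        ago_table = pd.DataFrame(0.0, index=list(AGOS), columns=list(SPECIES_COLS))
        ago_table.loc[["Ago1", "Ago3"], "precursor"] = 1.0
    else:
        ago_table = ago_partition(
            precursors[0],
            outcome_for_partition,
            ago3_residual=opt.ago3_residual,
            ago4_weight=opt.ago4_weight,
            ago2_knockout=opt.ago2_knockout,
        )
    if opt.ago2_knockout:
        # without slicer activity no Ago2-route species mature
        species = [s for s in species if s.name not in ("mature_guide", "intermediate")] \
            if category is not Category.DICER else species
    return ProcessingOutcome(
        design=design,
        category=category,
        species=species,
        ago_table=ago_table,
        loading=loading,
        diagnostics=diagnostics,
    )
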
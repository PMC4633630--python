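"""Desk-scale small-RNA-seq profiling of silencing constructs.

Re-implements the standard small-RNA library workflow at reference-table
scale: 3'-adaptor clipping with a minimum-length filter, collapsing to
unique sequences, sequential exact-match categorization against supplied
reference sets (construct -> miRNA -> tRNA -> rRNA -> snoRNA -> other ->
unmapped), 5'-anchored mature-miRNA counting with templated 3'
heterogeneity, per-million-miRNA normalization, and construct
end-heterogeneity (isoform) profiling.  A synthetic read generator turns
a simulated processing outcome into a FASTQ library for round-trip
validation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designer import GuideArm, HairpinDesign
from .processing import ProcessingOutcome
from .seqcore import FastqRead, NucSeq, write_fastq

logger = logging.getLogger(__name__)

MIN_ADAPTOR_MATCH = 6
MIN_READ_LEN = 19

CLASS_ORDER = ("construct", "miRNA", "tRNA", "rRNA", "snoRNA", "other", "unmapped")


class ProfilerError(ValueError):
    pass


@dataclass
class ReadSet:
    """Unique read sequences with multiplicities after preprocessing."""

    reads: dict[str, int]
    total_raw: int
    total_useful: int

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.reads.values()):
            raise ProfilerError("multiplicities must be >= 1")
        if self.total_useful > self.total_raw:
            raise ProfilerError("useful reads cannot exceed raw reads")


@dataclass
class MiRNAEntry:
    name: str
    precursor: str  # precursor sequence (RNA or DNA letters accepted)
    mature_start: int  # 1-based start of the mature miRNA on the precursor
    mature: str

    def __post_init__(self) -> None:
        self.precursor = self.precursor.upper().replace("T", "U")
        self.mature = self.mature.upper().replace("T", "U")
        end = self.mature_start - 1 + len(self.mature)
        if self.mature_start < 1 or end > len(self.precursor):
            raise ProfilerError(f"mature coordinates leave precursor for {self.name}")
        if self.precursor[self.mature_start - 1 : end] != self.mature:
            raise ProfilerError(f"mature sequence disagrees with precursor for {self.name}")

    @property
    def mature_end(self) -> int:
        return self.mature_start - 1 + len(self.mature)


@dataclass
class AnnotationSet:
    mirnas: list[MiRNAEntry] = field(default_factory=list)
    trnas: list[str] = field(default_factory=list)
    rrnas: list[str] = field(default_factory=list)
    snornas: list[str] = field(default_factory=list)
    other: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for attr in ("trnas", "rrnas", "snornas", "other"):
            setattr(
                self, attr, [s.upper().replace("T", "U") for s in getattr(self, attr)]
            )


def preprocess(
    raw_reads: list[str] | list[FastqRead],
    adaptor: str | NucSeq,
    min_len: int = MIN_READ_LEN,
) -> ReadSet:
    """Clip the 3' adaptor, drop unclippable/short reads, collapse.

    A read is clipped at the first occurrence of the adaptor's leading
    ``>=6``-nt prefix (no mismatches); reads without the adaptor, or
    shorter than ``min_len`` after clipping, are removed.
    """
    ad = str(adaptor).upper().replace("T", "U")
    if len(ad) < MIN_ADAPTOR_MATCH:
        raise ProfilerError(f"adaptor must be >= {MIN_ADAPTOR_MATCH} nt")
    probe = ad[:MIN_ADAPTOR_MATCH]
    counts: Counter[str] = Counter()
    total_raw = 0
    kept = 0
    for r in raw_reads:
        seq = (r.seq if isinstance(r, FastqRead) else r).upper().replace("T", "U")
        total_raw += 1
        i = seq.find(probe)
        if i == -1:
            continue
        insert = seq[:i]
        if len(insert) < min_len:
            continue
        counts[insert] += 1
        kept += 1
    return ReadSet(reads=dict(counts), total_raw=total_raw, total_useful=kept)


@dataclass
class CategoryCounts:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(CLASS_ORDER) - set(self.counts)
        for k in missing:
            self.counts[k] = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.counts[k] for k in CLASS_ORDER})


def classify(
    readset: ReadSet,
    annotations: AnnotationSet,
    construct: str | NucSeq | HairpinDesign | None = None,
) -> CategoryCounts:
    """Assign each unique read to the first matching class.

    Precedence: construct -> miRNA -> tRNA -> rRNA -> snoRNA -> other ->
    unmapped.  Matching is exact substring containment (0 mismatches) in
    any reference sequence of the class; counts are multiplicity-weighted
    and sum to the useful-read total.
    """
    refs: dict[str, list[str]] = {
        "construct": [],
        "miRNA": [e.precursor for e in annotations.mirnas],
        "tRNA": annotations.trnas,
        "rRNA": annotations.rrnas,
        "snoRNA": annotations.snornas,
        "other": annotations.other,
    }
    if construct is not None:
        cseq = construct.core if isinstance(construct, HairpinDesign) else construct
        refs["construct"] = [str(cseq).upper().replace("T", "U")]
    if not any(refs.values()):
        logger.warning("no reference sequences supplied; everything is unmapped")
    counts = {k: 0 for k in CLASS_ORDER}
    for seq, mult in readset.reads.items():
        for cls in CLASS_ORDER[:-1]:
            if any(seq in ref for ref in refs[cls]):
                counts[cls] += mult
                break
        else:
            counts["unmapped"] += mult
    return CategoryCounts(counts)


def count_mirna(readset: ReadSet, annotations: AnnotationSet) -> pd.Series:
    """5'-anchored mature-miRNA counting.

    A read counts toward a miRNA iff its 5' end coincides exactly with
    the annotated mature 5' start on the precursor and its 3' end lies
    within 2 nt of the mature 3' end; any 3' extension must be templated
    (match the precursor), which the anchored substring comparison
    enforces.  Untemplated additions are not counted.
    """
    out = {e.name: 0 for e in annotations.mirnas}
    for seq, mult in readset.reads.items():
        for e in annotations.mirnas:
            start = e.mature_start - 1
            if start + len(seq) > len(e.precursor):
                continue  # would require untemplated 3' residues
            if e.precursor[start : start + len(seq)] != seq:
                continue
            if abs((start + len(seq)) - e.mature_end) > 2:
                continue
            out[e.name] += mult
    return pd.Series(out, dtype=int)


def normalize_mirna(counts: pd.Series) -> pd.Series:
    """Counts per million miRNA reads: count / total * 1e6 (full precision)."""
    total = counts.sum()
    if total <= 0:
        raise ProfilerError("cannot normalize: total miRNA count is zero")
    return counts / total * 1_000_000


@dataclass
class IsoformTable:
    """(5' position, 3' position) isoform spectrum per construct strand."""

    per_strand: dict[str, pd.DataFrame]  # strand -> columns start, end, count, fraction
    homogeneity5: dict[str, float]  # fraction of reads sharing the modal 5' end
    top2: dict[str, list[tuple[int, int, float]]]


def end_heterogeneity(
    readset: ReadSet, construct: HairpinDesign | str
) -> IsoformTable:
    """Tabulate read 5'/3' ends on the construct and score 5' homogeneity.

    Reads mapping exactly (substring, 0 mismatches) inside the construct
    are assigned to the guide or passenger strand by which arm their 5'
    end falls in; isoform fractions sum to 1 per strand.
    """
    if isinstance(construct, HairpinDesign):
        cseq = construct.core.residues
        S, L = construct.stem_len, construct.loop_len
        five_arm_is_guide = construct.guide_arm is GuideArm.FIVE

        def strand_of(start: int) -> str:
            in_five = start <= S + L // 2
            if in_five:
                return "guide" if five_arm_is_guide else "passenger"
            return "passenger" if five_arm_is_guide else "guide"

    else:
        cseq = str(construct).upper().replace("T", "U")
        mid = len(cseq) // 2

        def strand_of(start: int) -> str:
            return "guide" if start <= mid else "passenger"

    spectra: dict[str, Counter] = {"guide": Counter(), "passenger": Counter()}
    for seq, mult in readset.reads.items():
        i = cseq.find(seq)
        if i == -1:
            continue
        start, end = i + 1, i + len(seq)  # 1-based inclusive
        spectra[strand_of(start)][(start, end)] += mult

    per_strand, homo, top2 = {}, {}, {}
    for strand, ctr in spectra.items():
        if not ctr:
            continue
        total = sum(ctr.values())
        rows = [
            {"start": s, "end": e, "count": c, "fraction": c / total}
            for (s, e), c in sorted(ctr.items())
        ]
        df = pd.DataFrame(rows)
        per_strand[strand] = df
        by5: Counter = Counter()
        for (s, _e), c in ctr.items():
            by5[s] += c
        homo[strand] = max(by5.values()) / total
        best = sorted(ctr.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
        top2[strand] = [(s, e, c / total) for (s, e), c in best]
    return IsoformTable(per_strand=per_strand, homogeneity5=homo, top2=top2)


# --------------------------------------------------------------------------
# Synthetic read generator
# --------------------------------------------------------------------------

@dataclass
class EndNoiseModel:
    """Independent 5'/3' end jitter applied to sampled reads.

    Each end is trimmed by one nucleotide with probability ``p5`` / ``p3``
    (resection-style heterogeneity; extensions are not modelled because a
    sampled species carries no sequence context beyond its own ends).
    """

    p5: float = 0.0
    p3: float = 0.0


def synth_reads(
    outcome: ProcessingOutcome,
    depth: int,
    adaptor: str = "UGGAAUUCUCGGGUGCCAAGG",
    noise: EndNoiseModel | None = None,
    rng_seed: int = 0,
    out_path: str | Path | None = None,
) -> list[FastqRead]:
    """Sample a FASTQ library from the species weights of a simulation.

    Reads are drawn multinomially in proportion to species weights, end
    jitter is applied per the noise model, and the 3' adaptor is appended
    (so the library round-trips through :func:`preprocess`).  Fully
    reproducible from ``rng_seed``; ``depth`` of zero yields no reads.
    """
    if not outcome.species:
        raise ProfilerError("outcome has no species to sample from")
    if depth < 0:
        raise ProfilerError("depth must be >= 0")
    nm = noise or EndNoiseModel()
    rng = np.random.default_rng(rng_seed)
    weights = np.array([s.weight for s in outcome.species], dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(depth, weights)
    reads: list[FastqRead] = []
    k = 0
    for spec, n in zip(outcome.species, counts):
        seq = spec.seq.residues
        for _ in range(n):
            s = seq
            if nm.p5 > 0 and rng.random() < nm.p5:
                s = s[1:]
            if nm.p3 > 0 and rng.random() < nm.p3:
                s = s[:-1]
            reads.append(
                FastqRead(
                    id=f"read{k:06d}_{spec.name}",
                    seq=s + adaptor.upper().replace("T", "U"),
                    quality="I" * (len(s) + len(adaptor)),
                )
            )
            k += 1
    if out_path is not None:
        write_fastq(reads, out_path)
    return reads
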
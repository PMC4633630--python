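"""Nucleic-acid sequence primitives shared by every stage of the toolkit.

All coordinates in this package are 1-based and inclusive on the 5'->3'
strand of the stated molecule; guide-strand positions number the guide 5'
end as position 1.  Designs are reported in the RNA alphabet, cloning
oligos in DNA; the two interconvert loss-lessly (T<->U).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# Watson-Crick partners, keyed by alphabet.
WC_PAIRS_RNA = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WC_PAIRS_DNA = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class AlphabetError(ValueError):
    """Raised when a residue falls outside the declared alphabet."""


class FastaError(ValueError):
    """Raised for malformed FASTA input (e.g. duplicate record ids)."""


class FastqError(ValueError):
    """Raised for malformed FASTQ input."""


@dataclass(frozen=True)
class NucSeq:
    """An immutable 5'->3' nucleotide sequence with an explicit alphabet.

    Parameters
    ----------
    residues:
        Upper-case sequence string over {A,C,G,T} (DNA) or {A,C,G,U} (RNA).
    alphabet:
        ``"DNA"`` or ``"RNA"``.  Inferred from the residues when omitted
        (a sequence without T or U defaults to the declared alphabet RNA
        only if requested explicitly; the constructor requires it).
    """

    residues: str
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        if not self.residues:
            raise ValueError("empty sequence")
        allowed = DNA_BASES if self.alphabet == "DNA" else RNA_BASES
        for i, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise AlphabetError(
                    f"invalid {self.alphabet} residue {ch!r} at position {i}"
                )

    # -- dunder conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def __contains__(self, sub) -> bool:
        return str(sub) in self.residues

    # -- conversions ---------------------------------------------------------
    def to_rna(self) -> "NucSeq":
        if self.alphabet == "RNA":
            return self
        return NucSeq(self.residues.replace("T", "U"), "RNA")

    def to_dna(self) -> "NucSeq":
        if self.alphabet == "DNA":
            return self
        return NucSeq(self.residues.replace("U", "T"), "DNA")

    def complement(self) -> "NucSeq":
        table = _DNA_COMPLEMENT if self.alphabet == "DNA" else _RNA_COMPLEMENT
        return NucSeq(self.residues.translate(table), self.alphabet)

    def revcomp(self) -> "NucSeq":
        table = _DNA_COMPLEMENT if self.alphabet == "DNA" else _RNA_COMPLEMENT
        return NucSeq(self.residues.translate(table)[::-1], self.alphabet)

    # -- simple metrics ------------------------------------------------------
    def gc_fraction(self) -> float:
        n = len(self.residues)
        return (self.residues.count("G") + self.residues.count("C")) / n

    def max_homopolymer(self, base: str | None = None) -> int:
        """Longest run of a single base (or of ``base`` if given)."""
        best = run = 0
        prev = ""
        for ch in self.residues:
            run = run + 1 if ch == prev else 1
            prev = ch
            if base is None or ch == base:
                best = max(best, run)
        return best


def revcomp(s: NucSeq) -> NucSeq:
    """Reverse complement in the same alphabet; length preserved."""
    return s.revcomp()


def is_wc_pair(a: str, b: str, alphabet: str = "RNA") -> bool:
    pairs = WC_PAIRS_RNA if alphabet == "RNA" else WC_PAIRS_DNA
    return (a, b) in pairs


@dataclass(frozen=True)
class EndChemistry:
    """Terminal chemistry of an RNA molecule.

    5' end: ``PPP`` (triphosphate, nascent transcript), ``P`` (monophosphate)
    or ``OH``.  3' end: ``OH``, ``CyclicP`` (2',3'-cyclic phosphate left by
    ribozyme self-scission) or ``P``.
    """

    five_prime: str = "PPP"
    three_prime: str = "OH"

    _FIVE = ("PPP", "P", "OH")
    _THREE = ("OH", "CyclicP", "P")

    def __post_init__(self) -> None:
        if self.five_prime not in self._FIVE:
            raise ValueError(f"bad 5' chemistry {self.five_prime!r}")
        if self.three_prime not in self._THREE:
            raise ValueError(f"bad 3' chemistry {self.three_prime!r}")


@dataclass
class SeqRecord:
    """A named sequence; ids are unique within one file."""

    id: str
    seq: NucSeq
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")


def _clean(raw: str, alphabet: str, permissive: bool, path, warned: list) -> str:
    s = str(raw)
    if s != s.upper():
        if not warned:
            logger.warning("lowercase residues in %s uppercased", path)
            warned.append(True)
        s = s.upper()
    if alphabet == "RNA":
        s = s.replace("T", "U")
    allowed = DNA_BASES if alphabet == "DNA" else RNA_BASES
    bad = [i for i, ch in enumerate(s, 1) if ch not in allowed]
    if bad and not permissive:
        raise AlphabetError(
            f"invalid {alphabet} residue at position {bad[0]} in {path}"
        )
    return s


def read_fasta(
    path: str | Path, alphabet: str = "DNA", permissive: bool = False
) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Duplicate ids raise :class:`FastaError`; an empty file yields an empty
    list.  Under ``permissive=True`` IUPAC ambiguity codes are tolerated
    (they are excluded from design windows downstream).
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: dict[str, int] = {}
    warned: list = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seen[rec.id] = seen.get(rec.id, 0) + 1
            s = _clean(rec.seq, alphabet, permissive, path, warned)
            if permissive:
                # keep only records we can represent; ambiguity codes pass
                # through as raw strings attached to the description
                allowed = DNA_BASES if alphabet == "DNA" else RNA_BASES
                if any(ch not in allowed for ch in s):
                    logger.warning("record %s contains ambiguity codes", rec.id)
                    continue
            records.append(SeqRecord(rec.id, NucSeq(s, alphabet), rec.description))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FastaError(f"duplicate FASTA ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.seq.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


@dataclass
class FastqRead:
    id: str
    seq: str
    quality: str


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Read 4-line FASTQ (optionally gzip-compressed).

    Qualities are carried but unused downstream; a truncated record or a
    quality string whose length differs from the sequence raises
    :class:`FastqError` with the offending line number.
    """
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    reads: list[FastqRead] = []
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # drop a single trailing blank line, a common artefact
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FastqError(f"truncated FASTQ record near line {len(lines) + 1}")
    for i in range(0, len(lines), 4):
        hdr, seq, plus, qual = lines[i : i + 4]
        if not hdr.startswith("@") or not plus.startswith("+"):
            raise FastqError(f"malformed FASTQ record at line {i + 1}")
        if len(seq) != len(qual):
            raise FastqError(
                f"quality length != sequence length at line {i + 4}"
            )
        reads.append(FastqRead(hdr[1:].split()[0], seq.upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.quality}\n")
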
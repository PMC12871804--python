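"""Genomic coordinate primitives shared by all stages.

Internally everything is 0-based half-open on the plus-strand genome axis;
transcript orientation is derived from ``strand`` at operation time.
On-disk dialects (GTF, SJ tables: 1-based inclusive) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

_STRANDS = {"+", "-"}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (case preserving; N self-complementary)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeAccessor(Protocol):
    """Anything that can return plus-strand sequence for a region."""

    def fetch(self, chrom: str, start: int, end: int) -> str:  # pragma: no cover
        ...


class DictGenome:
    """In-memory genome backed by a dict of chromosome sequences."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class GeneModel:
    """Exon/CDS structure of one locus.

    ``exons`` and ``cds`` are ordered 5'->3' in transcript orientation, so
    for a minus-strand gene the genomic coordinates descend along the list.
    """

    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    genome: GenomeAccessor | None = None

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self._check_ordered(self.exons, "exons")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"CDS segment {c} not contained in any exon")

    def _check_ordered(self, ivs: list[GenomicInterval], what: str) -> None:
        for a, b in zip(ivs, ivs[1:]):
            if self.strand == "+":
                ok = a.end <= b.start
            else:
                ok = b.end <= a.start
            if not ok:
                raise ValueError(f"{what} must be ordered 5'->3' and non-overlapping")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def exon_sequence(self, i: int) -> str:
        e = self.exons[i]
        seq = self.genome.fetch(e.chrom, e.start, e.end)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_sequence(self, through_exon: int | None = None) -> str:
        """Concatenated CDS in transcript orientation, optionally limited to
        CDS segments lying in exons[0..through_exon]."""
        if self.genome is None:
            raise ValueError("gene model has no genome accessor")
        segs = self.cds
        if through_exon is not None:
            keep = self.exons[: through_exon + 1]
            segs = [
                c
                for c in segs
                if any(e.start <= c.start and c.end <= e.end for e in keep)
            ]
        parts = []
        for c in segs:
            s = self.genome.fetch(c.chrom, c.start, c.end)
            parts.append(revcomp(s) if self.strand == "-" else s)
        return "".join(parts)

    def intron_after(self, exon_index: int) -> GenomicInterval:
        """The intron between exons[exon_index] and exons[exon_index + 1]."""
        a = self.exons[exon_index]
        b = self.exons[exon_index + 1]
        if self.strand == "+":
            return GenomicInterval(a.chrom, a.end, b.start, "+")
        return GenomicInterval(a.chrom, b.end, a.start, "-")
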
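"""Polyadenylation-signal discovery and truncated-isoform prediction.

A polyadenylation signal (PAS) is a hexamer — canonically AATAAA — that
directs cleavage and polyadenylation of the nascent transcript roughly
20 nt downstream.  An intronic PAS (iPAS) truncates the transcript: the
open reading frame runs from the last shared exon into the intron up to the
first in-frame stop codon, producing a short protein with a unique
C-terminal tail peptide and an intron-derived 3'UTR.

This module finds PAS hexamers (including partially overlapping runs, the
typical signature of an A-rich repeat tail), clusters them, predicts the
cleavage site with a fixed-offset heuristic, annotates overlap with
repeat elements, and predicts the truncated isoform.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from ipastrace.intervals import GeneModel, GenomicInterval, revcomp

#: The canonical polyadenylation signal used by default.
CANONICAL_PAS = "AATAAA"

#: The 12 common PAS hexamer variants (canonical first); enabled by flag.
PAS_VARIANTS = (
    "AATAAA",
    "ATTAAA",
    "TATAAA",
    "AGTAAA",
    "AAGAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
)

_VALID = set("ACGTN")


class NonStopError(ValueError):
    """Raised when no in-frame stop codon occurs before the cleavage site."""


@dataclass(frozen=True)
class PasHit:
    """One PAS hexamer occurrence."""

    interval: GenomicInterval
    motif: str
    motif_class: str  # "canonical" or "variant"
    distance_to_upstream_exon: int | None = None

    def __post_init__(self) -> None:
        if len(self.motif) != 6 or len(self.interval) != 6:
            raise ValueError("PAS hits are hexamers")


@dataclass
class PasCluster:
    """A maximal group of PAS hits chained by >=1 nt overlaps."""

    hits: list[PasHit]
    cleavage_site: int | None = None
    repeat_name: str | None = None
    repeat_class: str | None = None

    @property
    def n_signals(self) -> int:
        return len(self.hits)

    @property
    def interval(self) -> GenomicInterval:
        first = self.hits[0].interval
        return GenomicInterval(
            first.chrom,
            min(h.interval.start for h in self.hits),
            max(h.interval.end for h in self.hits),
            first.strand,
        )


@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat element placement (e.g. from RepeatMasker)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str


@dataclass
class TruncatedIsoformPrediction:
    """The protein/UTR anatomy of the iPAS-truncated isoform."""

    stop_codon: GenomicInterval
    tail_peptide: str
    utr3: GenomicInterval
    protein: str
    protein_mw: float
    common_residues: int = 0

    @property
    def tail_length(self) -> int:
        return len(self.tail_peptide)

    @property
    def utr3_length(self) -> int:
        return len(self.utr3)

    @property
    def protein_length(self) -> int:
        return len(self.protein)


def scan_pas(
    seq: str,
    motifs: tuple[str, ...] | set[str] = (CANONICAL_PAS,),
    allow_overlap: bool = True,
    chrom: str = ".",
    origin: int = 0,
    strand: str = "+",
) -> list[PasHit]:
    """Find every PAS hexamer occurrence in ``seq``.

    ``seq`` is scanned in the orientation given; coordinates are reported on
    the plus-strand genome axis assuming ``seq`` starts at ``origin`` when
    ``strand == '+'`` and *ends* at ``origin + len(seq)`` with ``seq`` being
    the reverse complement of the region when ``strand == '-'``.  Matching is
    case-insensitive (soft-masked repeat sequence is this module's main
    subject); N never matches.
    """
    if not motifs:
        raise ValueError("motif set must be non-empty")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at offset {i}")
    hits: list[PasHit] = []
    for motif in sorted(set(m.upper() for m in motifs)):
        if len(motif) != 6:
            raise ValueError(f"PAS motifs are hexamers, got {motif!r}")
        pos = up.find(motif)
        while pos != -1:
            hits.append(_make_hit(pos, motif, chrom, origin, strand, len(seq)))
            step = 1 if allow_overlap else len(motif)
            pos = up.find(motif, pos + step)
    hits.sort(key=lambda h: (h.interval.start, h.motif))
    if not allow_overlap:
        pruned: list[PasHit] = []
        for h in hits:
            if not pruned or h.interval.start >= pruned[-1].interval.end:
                pruned.append(h)
        hits = pruned
    return hits


def _make_hit(
    pos: int, motif: str, chrom: str, origin: int, strand: str, seq_len: int
) -> PasHit:
    cls = "canonical" if motif == CANONICAL_PAS else "variant"
    if strand == "+":
        iv = GenomicInterval(chrom, origin + pos, origin + pos + 6, "+")
    else:
        # position pos in the reverse-complemented sequence maps to
        # genomic [origin + seq_len - pos - 6, origin + seq_len - pos)
        g_end = origin + seq_len - pos
        iv = GenomicInterval(chrom, g_end - 6, g_end, "-")
    return PasHit(interval=iv, motif=motif, motif_class=cls)


def scan_region(
    genome,
    region: GenomicInterval,
    motifs: tuple[str, ...] | set[str] = (CANONICAL_PAS,),
    allow_overlap: bool = True,
) -> list[PasHit]:
    """Scan a genomic region in transcript orientation."""
    seq = genome.fetch(region.chrom, region.start, region.end)
    if region.strand == "-":
        seq = revcomp(seq)
    return scan_pas(
        seq,
        motifs,
        allow_overlap,
        chrom=region.chrom,
        origin=region.start,
        strand=region.strand,
    )


def cluster_hits(hits: list[PasHit]) -> list[PasCluster]:
    """Partition hits into maximal chains of >=1 nt pairwise overlaps.

    Transitive closure: a hit joins a cluster if it overlaps the cluster's
    running envelope, which for sorted fixed-length hits equals overlap with
    the previous hit.  Singletons form singleton clusters.
    """
    clusters: list[PasCluster] = []
    for hit in sorted(hits, key=lambda h: h.interval.start):
        if clusters and clusters[-1].hits[-1].interval.overlaps(hit.interval):
            clusters[-1].hits.append(hit)
        else:
            clusters.append(PasCluster(hits=[hit]))
    return clusters


def predict_cleavage_site(cluster: PasCluster, offset_nt: int = 20) -> int:
    """Predict the cleavage/poly(A) site of a PAS cluster.

    The site is placed ``offset_nt`` downstream (transcript orientation) of
    the *end* of the 5'-most hexamer — the fixed-offset heuristic that
    encodes the canonical ~20 nt PAS-to-cleavage spacing.
    """
    if not cluster.hits:
        raise ValueError("cannot predict a cleavage site for an empty cluster")
    if offset_nt < 0:
        raise ValueError("offset must be >= 0")
    strand = cluster.hits[0].interval.strand
    if strand == "+":
        first = min(cluster.hits, key=lambda h: h.interval.start)
        return first.interval.end + offset_nt
    first = max(cluster.hits, key=lambda h: h.interval.end)
    return first.interval.start - offset_nt


def annotate_repeat_overlap(
    clusters: list[PasCluster], repeats: list[RepeatAnnotation]
) -> list[PasCluster]:
    """Attach to each cluster the repeat with maximal overlap (ties: first
    by coordinate); clusters overlapping nothing keep empty annotation."""
    out = []
    for cl in clusters:
        env = cl.interval
        best: RepeatAnnotation | None = None
        best_ov = 0
        for rep in sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start)):
            ov = env.overlap_length(rep.interval)
            if ov > best_ov:
                best, best_ov = rep, ov
        annotated = PasCluster(
            hits=list(cl.hits),
            cleavage_site=cl.cleavage_site,
            repeat_name=best.repeat_name if best else None,
            repeat_class=best.repeat_class if best else None,
        )
        out.append(annotated)
    return out


def extend_orf_into_intron(
    model: GeneModel,
    last_common_exon: int,
    cleavage_site: int,
    max_tail_nt: int | None = None,
) -> TruncatedIsoformPrediction:
    """Predict the truncated isoform created by an iPAS in the intron after
    ``last_common_exon`` (0-based exon index).

    Translation proceeds through the CDS of exons ``0..last_common_exon``;
    any partial codon at the exon boundary is completed with intronic bases,
    and codons are then read into the intron until the first stop codon.
    The tail peptide is the run of residues whose codons contain at least
    one intronic base — the portion unique to the truncated isoform.  The
    3'UTR runs from the stop codon to the cleavage site.
    """
    if model.genome is None:
        raise ValueError("gene model needs a genome accessor")
    cds = model.cds_sequence(through_exon=last_common_exon)
    exon = model.exons[last_common_exon]
    intron_iv = _intron_from(model, last_common_exon, cleavage_site)
    intron_seq = model.genome.fetch(intron_iv.chrom, intron_iv.start, intron_iv.end)
    if model.strand == "-":
        intron_seq = revcomp(intron_seq)

    n_complete = len(cds) // 3
    carry = cds[n_complete * 3 :]  # partial codon crossing the junction
    common_protein = str(Seq(cds[: n_complete * 3]).translate())
    if "*" in common_protein:
        raise ValueError("internal stop codon within the shared CDS")

    tail_coding = carry + intron_seq
    tail_residues = []
    stop_offset_in_intron: int | None = None
    for i in range(0, len(tail_coding) - 2, 3):
        codon = tail_coding[i : i + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            stop_offset_in_intron = i + 3 - len(carry)  # intronic nt consumed
            break
        tail_residues.append(aa)
        if max_tail_nt is not None and i > max_tail_nt:
            break
    if stop_offset_in_intron is None:
        raise NonStopError(
            "no in-frame stop codon between the exon boundary and the cleavage site"
        )
    tail_peptide = "".join(tail_residues)

    if model.strand == "+":
        stop_iv = GenomicInterval(
            exon.chrom,
            exon.end + stop_offset_in_intron - 3,
            exon.end + stop_offset_in_intron,
            "+",
        )
        utr3 = GenomicInterval(exon.chrom, stop_iv.end, cleavage_site, "+")
    else:
        stop_iv = GenomicInterval(
            exon.chrom,
            exon.start - stop_offset_in_intron,
            exon.start - stop_offset_in_intron + 3,
            "-",
        )
        utr3 = GenomicInterval(exon.chrom, cleavage_site, stop_iv.start, "-")

    protein = common_protein + tail_peptide
    mw = molecular_weight(protein, seq_type="protein")  # average isotopic
    return TruncatedIsoformPrediction(
        stop_codon=stop_iv,
        tail_peptide=tail_peptide,
        utr3=utr3,
        protein=protein,
        protein_mw=mw,
        common_residues=len(common_protein),
    )


def _intron_from(
    model: GeneModel, exon_index: int, cleavage_site: int
) -> GenomicInterval:
    """Intronic interval from the end of exons[exon_index] to the cleavage
    site (transcript orientation)."""
    exon = model.exons[exon_index]
    if model.strand == "+":
        if cleavage_site <= exon.end:
            raise ValueError("cleavage site must lie downstream of the exon")
        return GenomicInterval(exon.chrom, exon.end, cleavage_site, "+")
    if cleavage_site >= exon.start:
        raise ValueError("cleavage site must lie downstream of the exon")
    return GenomicInterval(exon.chrom, cleavage_site, exon.start, "-")
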
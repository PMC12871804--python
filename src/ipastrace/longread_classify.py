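"""Long-read exon-chain collapse and isoform classification.

Long cDNA reads aligned to a locus are summarized by their exon chains
(ordered genomic exon blocks).  Reads with identical internal splice
junctions represent the same isoform up to terminal-end jitter; collapsing
groups them and picks the longest-span representative.  Classification
compares each read against reference isoform models: a truncated isoform's
only distinguishing feature is its 3' terminus, so calls are conservative —
reads compatible with more than one model (e.g. 3'-truncation artifacts
covering only shared junctions) are "ambiguous", never evidence for the
short isoform.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ExonChain:
    """Ordered exon blocks of one read or isoform model on the genome axis.

    ``exons`` are (start, end) half-open pairs in ascending genomic order
    regardless of strand; ``strand`` orients 5'/3' logic.
    """

    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    name: str = ""

    def __post_init__(self) -> None:
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError("exon start must precede end")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError("exons must be ascending and non-overlapping")

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Internal junctions as (donor, acceptor) genomic coordinate pairs."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' terminus."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def five_prime(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]


@dataclass
class IsoformModel:
    """A named reference isoform (e.g. canonical vs short)."""

    name: str
    chain: ExonChain

    @property
    def three_prime(self) -> int:
        return self.chain.three_prime


def collapse_chains(
    reads: list[ExonChain], end_tolerance_nt: int = 50
) -> list[tuple[ExonChain, int]]:
    """Collapse reads into unique isoforms.

    Reads group by identical internal-junction chains; within a junction
    group, terminal ends merge by single linkage when both ends agree within
    ``end_tolerance_nt``.  The representative is the longest-span member;
    groups are returned by decreasing support.
    """
    by_junctions: dict[tuple, list[ExonChain]] = {}
    for r in reads:
        by_junctions.setdefault((r.chrom, r.strand, r.junctions), []).append(r)

    collapsed: list[tuple[ExonChain, int]] = []
    for group in by_junctions.values():
        for sub in _merge_by_ends(group, end_tolerance_nt):
            rep = max(sub, key=lambda c: c.span[1] - c.span[0])
            collapsed.append((rep, len(sub)))
    collapsed.sort(key=lambda t: (-t[1], t[0].span))
    return collapsed


def _merge_by_ends(group: list[ExonChain], tol: int) -> list[list[ExonChain]]:
    """Single-linkage clustering of same-junction reads by terminal ends."""
    clusters: list[list[ExonChain]] = []
    for read in group:
        s, e = read.span
        merged = None
        for cl in clusters:
            if any(
                abs(s - c.span[0]) <= tol and abs(e - c.span[1]) <= tol for c in cl
            ):
                if merged is None:
                    cl.append(read)
                    merged = cl
                else:  # read links two clusters: fuse them
                    merged.extend(cl)
                    cl.clear()
        clusters = [c for c in clusters if c]
        if merged is None:
            clusters.append([read])
    return clusters


def classify_read(
    read: ExonChain,
    models: list[IsoformModel],
    junction_tolerance_nt: int = 0,
    terminal_tolerance_nt: int = 50,
) -> str:
    """Label a read against reference isoform models.

    A read *fully matches* a model when (i) its junctions are an in-order
    subset of the model's junctions within ``junction_tolerance_nt``, (ii)
    it never reads through a model intron, and (iii) its 3' terminus lies
    within ``terminal_tolerance_nt`` of the model's.  The 5' end is left
    free (cDNA reads are frequently 5'-degraded).

    Returns the unique fully matching model's name; "ambiguous" when more
    than one model fully matches or when the read is a truncation-compatible
    fragment of at least one model; "novel" otherwise.
    """
    if not models:
        raise ValueError("at least one isoform model is required")
    full, truncated = [], []
    for m in models:
        if read.chrom != m.chain.chrom or read.strand != m.chain.strand:
            continue
        if not _structure_compatible(read, m.chain, junction_tolerance_nt):
            continue
        d3 = abs(read.three_prime - m.three_prime)
        if d3 <= terminal_tolerance_nt:
            full.append(m.name)
        elif _ends_before(read, m.chain):
            truncated.append(m.name)
    if len(full) == 1:
        return full[0]
    if len(full) > 1 or truncated:
        return "ambiguous"
    return "novel"


def _structure_compatible(read: ExonChain, model: ExonChain, jt: int) -> bool:
    """Read junctions match an in-order subset of model junctions and the
    read does not read through any model intron (beyond tolerance)."""
    mj = model.junctions
    j = 0
    for (d, a) in read.junctions:
        while j < len(mj) and not (abs(mj[j][0] - d) <= jt and abs(mj[j][1] - a) <= jt):
            j += 1
        if j == len(mj):
            return False
        j += 1
    # intron read-through check: no model junction may fall strictly inside
    # a read exon unless matched above
    matched = set()
    for (d, a) in read.junctions:
        for k, (md, ma) in enumerate(mj):
            if abs(md - d) <= jt and abs(ma - a) <= jt:
                matched.add(k)
    for k, (md, ma) in enumerate(mj):
        if k in matched:
            continue
        for (s, e) in read.exons:
            if s + jt < md < e - jt or s + jt < ma < e - jt:
                return False
    return True


def _ends_before(read: ExonChain, model: ExonChain) -> bool:
    """True when the read's 3' end stops short of the model's terminus
    (a 3'-truncation artifact rather than an extension past it)."""
    if read.strand == "+":
        return read.three_prime <= model.three_prime
    return read.three_prime >= model.three_prime
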
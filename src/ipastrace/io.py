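"""Shared format readers and writers.

On-disk dialects and their conversions:

- FASTA: plain sequence, via Biopython / pyfaidx.
- GTF: 1-based inclusive coordinates, converted to the internal 0-based
  half-open representation on read (gffutils backend).
- Repeat annotations: BED6 (0-based half-open) or RepeatMasker ``.out``
  tables (1-based inclusive), auto-detected.
- BED12: 0-based half-open blocks for long-read exon chains and models.
- Character matrix: TSV with columns tip / presence / count (NA allowed).
- All output tables are TSV with a commented header naming units and
  coordinate conventions.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils

from ipastrace.intervals import GeneModel, GenomicInterval
from ipastrace.longread_classify import ExonChain, IsoformModel
from ipastrace.pas_scan import RepeatAnnotation


class FastaGenome:
    """Genome accessor over an on-disk FASTA file (pyfaidx-backed)."""

    def __init__(self, path):
        import pyfaidx

        self.fasta = pyfaidx.Fasta(str(path))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self.fasta[chrom][start:end])


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------- gene models


def read_gtf(path, gene_id: str, genome=None) -> GeneModel:
    """Build a :class:`GeneModel` for one gene from a GTF file."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons, cds, strand = [], [], "+"
    found = False
    for feat in db.all_features():
        if feat.attributes.get("gene_id", [None])[0] != gene_id:
            continue
        found = True
        strand = feat.strand
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "exon":
            exons.append(iv)
        elif feat.featuretype == "CDS":
            cds.append(iv)
    if not found:
        raise ValueError(f"gene {gene_id!r} not found in {path}")
    reverse = strand == "-"
    exons.sort(key=lambda e: e.start, reverse=reverse)
    cds.sort(key=lambda c: c.start, reverse=reverse)
    return GeneModel(gene_id=gene_id, strand=strand, exons=exons, cds=cds, genome=genome)


def write_gtf(path, model: GeneModel, transcript_id: str | None = None) -> None:
    """Write a gene model as GTF (1-based inclusive on disk)."""
    tid = transcript_id or f"{model.gene_id}.t1"
    attrs = f'gene_id "{model.gene_id}"; transcript_id "{tid}";'
    rows = []
    for kind, ivs in (("exon", model.exons), ("CDS", model.cds)):
        for iv in ivs:
            rows.append(
                (iv.chrom, "ipastrace", kind, iv.start + 1, iv.end, ".", model.strand, ".", attrs)
            )
    rows.sort(key=lambda r: r[3])
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


# ------------------------------------------------------------------- repeats


def read_repeats(path) -> list[RepeatAnnotation]:
    """Read repeat annotations from BED6 or a RepeatMasker ``.out`` table."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if _looks_like_repeatmasker(lines):
        return _parse_rm_out(lines)
    return _parse_repeat_bed(lines)


def _looks_like_repeatmasker(lines: list[str]) -> bool:
    head = lines[0].split()
    return bool(head) and (head[0].lower() in ("sw", "score") or head[0].isdigit() and len(lines[0].split()) >= 11)


def _parse_repeat_bed(lines: list[str]) -> list[RepeatAnnotation]:
    out = []
    for ln in lines:
        if ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        if len(f) < 4:
            f = ln.split()
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
        # BED name column may carry name#class
        rep_name, _, rep_class = name.partition("#")
        out.append(
            RepeatAnnotation(
                interval=GenomicInterval(chrom, start, end, strand),
                repeat_name=rep_name,
                repeat_class=rep_class or "Unknown",
            )
        )
    return out


def _parse_rm_out(lines: list[str]) -> list[RepeatAnnotation]:
    out = []
    for ln in lines:
        f = ln.split()
        if not f or not f[0].isdigit():
            continue  # header lines
        chrom, start1, end1 = f[4], int(f[5]), int(f[6])
        strand = "-" if f[8] in ("C", "-") else "+"
        rep_name, rep_class = f[9], f[10]
        out.append(
            RepeatAnnotation(
                interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                repeat_name=rep_name,
                repeat_class=rep_class,
            )
        )
    return out


# --------------------------------------------------------------------- BED12


def read_bed12(path) -> list[ExonChain]:
    """Read exon chains from a BED12 file (0-based half-open blocks)."""
    chains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            chains.append(ExonChain(chrom=chrom, strand=strand, exons=exons, name=name))
    return chains


def write_bed12(path, chains: list[ExonChain], scores: list[int] | None = None) -> None:
    with open(path, "w") as fh:
        for i, ch in enumerate(chains):
            start, end = ch.span
            sizes = ",".join(str(e - s) for s, e in ch.exons)
            offsets = ",".join(str(s - start) for s, _ in ch.exons)
            score = scores[i] if scores else 0
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            ch.chrom,
                            start,
                            end,
                            ch.name or f"read{i}",
                            score,
                            ch.strand,
                            start,
                            end,
                            "0,0,0",
                            len(ch.exons),
                            sizes + ",",
                            offsets + ",",
                        ],
                    )
                )
                + "\n"
            )


def read_isoform_models(path) -> list[IsoformModel]:
    return [IsoformModel(name=ch.name, chain=ch) for ch in read_bed12(path)]


# ---------------------------------------------------------- character matrix


def read_character_matrix(path) -> dict[str, tuple[str, int | None]]:
    """Read a tip character TSV: columns tip, presence, count (NA allowed)."""
    chars: dict[str, tuple[str, int | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0].lower() in ("tip", "species"):
                continue
            tip, presence = f[0], f[1].lower()
            count = None if f[2].upper() in ("NA", "NAN", "") else int(f[2])
            chars[tip] = (presence, count)
    return chars


def write_tsv(path, df, comment: str = "") -> None:
    """Write a DataFrame as TSV with an optional commented header line."""
    with open(path, "w") as fh:
        if comment:
            for ln in comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
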
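"""Isoform usage from exon-exon junction read counts.

A truncated isoform that terminates in an intron contributes reads only to
the junctions upstream of its termination site.  If a fraction psi of
transcripts terminate early, junctions shared by both isoforms see reads
from all transcripts while downstream junctions (exclusive to the
full-length isoform) see only the 1 - psi that read through, so

    E[mean(down)] / E[mean(up)] = 1 - psi

which motivates the moment estimator psi_hat = 1 - mean(down)/mean(up),
clipped to [0, 1].  Confidence intervals come from a multinomial bootstrap
over junction counts; a chi-square goodness-of-fit against the
equal-expectation model tests for any departure from "no truncation".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction with read support (internal 0-based half-open)."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int
    multi_reads: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError("intron start must not exceed intron end")
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ValueError("junction read counts must be non-negative")


@dataclass
class JunctionUsageProfile:
    """Per-junction counts expressed as percentages of the total."""

    labels: list[str]
    counts: np.ndarray
    percentages: np.ndarray


@dataclass
class IsoformFractionEstimate:
    """Short-isoform fraction psi_hat with bootstrap CI and uniformity test."""

    psi_hat: float
    ci_low: float
    ci_high: float
    n_up: int
    n_down: int
    p_uniform: float
    psi_raw: float  # un-clipped; negative values flag down > up sampling noise
    n_boot: int = 0


_STRAND_CODES = {"0": ".", "1": "+", "2": "-"}


def read_sj_table(path) -> list[JunctionRecord]:
    """Read a STAR ``SJ.out.tab`` splice-junction table.

    On disk the intron coordinates are 1-based inclusive; they are converted
    to 0-based half-open on read.  Column 7 (uniquely mapping reads) is the
    default count used downstream; multi-mappers (column 8) are kept but
    ignored unless asked for.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected >=9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start1, end1 = int(fields[1]), int(fields[2])
                uniq, multi = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})")
            if uniq < 0 or multi < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            records.append(
                JunctionRecord(
                    chrom=fields[0],
                    intron_start=start1 - 1,
                    intron_end=end1,
                    strand=_STRAND_CODES.get(fields[3], "."),
                    unique_reads=uniq,
                    multi_reads=multi,
                )
            )
    return records


def junction_percentages(
    counts, labels: list[str] | None = None
) -> JunctionUsageProfile:
    """Express per-junction counts as percentages of total junction reads."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("junction counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero junction counts give an undefined profile")
    if labels is None:
        labels = [f"J{i + 1}" for i in range(arr.size)]
    return JunctionUsageProfile(
        labels=list(labels), counts=arr, percentages=100.0 * arr / total
    )


def estimate_short_fraction(
    up_counts,
    down_counts,
    n_boot: int = 2000,
    seed: int | None = None,
    exact_below: int = 500,
) -> IsoformFractionEstimate:
    """Estimate the short-isoform fraction psi from junction counts.

    ``up_counts`` are junctions shared by both isoforms; ``down_counts`` are
    exclusive to the full-length isoform.  The percentile bootstrap resamples
    reads over junctions (multinomial at the observed total).  The
    no-truncation test is a chi-square goodness of fit of all counts against
    equal expectations; for small totals (< ``exact_below``) the p-value is
    instead obtained from the exact multinomial null via seeded Monte-Carlo
    sampling (the chi-square statistic as discrepancy measure).
    """
    up = np.asarray(up_counts, dtype=float)
    down = np.asarray(down_counts, dtype=float)
    if up.size == 0 or down.size == 0:
        raise ValueError("need at least one junction in each group")
    if (up < 0).any() or (down < 0).any():
        raise ValueError("junction counts must be non-negative")
    if up.mean() == 0:
        raise ValueError("zero upstream coverage: psi is undefined")

    psi_raw = 1.0 - down.mean() / up.mean()
    psi_hat = float(np.clip(psi_raw, 0.0, 1.0))

    counts = np.concatenate([up, down])
    total = counts.sum()
    k_up = up.size

    ci_low = ci_high = psi_hat
    if n_boot > 0 and total > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(int(total), counts / total, size=n_boot).astype(float)
        up_b = draws[:, :k_up].mean(axis=1)
        down_b = draws[:, k_up:].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            psi_b = 1.0 - down_b / up_b
        psi_b = np.clip(psi_b[np.isfinite(psi_b)], 0.0, 1.0)
        if psi_b.size:
            ci_low, ci_high = (float(q) for q in np.quantile(psi_b, [0.025, 0.975]))

    p_uniform = _uniformity_pvalue(counts, exact_below, seed)

    return IsoformFractionEstimate(
        psi_hat=psi_hat,
        ci_low=min(ci_low, psi_hat),
        ci_high=max(ci_high, psi_hat),
        n_up=int(up.sum()),
        n_down=int(down.sum()),
        p_uniform=p_uniform,
        psi_raw=float(psi_raw),
        n_boot=n_boot,
    )


def _uniformity_pvalue(counts: np.ndarray, exact_below: int, seed) -> float:
    total = counts.sum()
    if total <= 0:
        return 1.0
    expected = np.full(counts.size, total / counts.size)
    chi2_obs = ((counts - expected) ** 2 / expected).sum()
    if total >= exact_below:
        return float(stats.chisquare(counts, expected).pvalue)
    # exact multinomial null, Monte-Carlo evaluated (chi-square discrepancy)
    rng = np.random.default_rng(seed if seed is None else seed + 1)
    n_sim = 20000
    sims = rng.multinomial(int(total), expected / total, size=n_sim).astype(float)
    chi2_sim = ((sims - expected) ** 2 / expected).sum(axis=1)
    return float((1 + (chi2_sim >= chi2_obs - 1e-12).sum()) / (1 + n_sim))


@dataclass
class ExonInclusionProfile:
    """pext-style per-tissue exon inclusion with cross-tissue summary."""

    exon_id: str
    per_tissue: pd.Series
    mean: float
    sd: float


def pext_like(
    transcript_tpm: pd.DataFrame,
    transcripts_with_exon,
    exon_id: str = "exon",
) -> ExonInclusionProfile:
    """Proportion of a gene's expression carried by transcripts containing
    the exon (pext: "proportion expressed across transcripts").

    ``transcript_tpm`` is a transcripts x tissues TPM table;
    ``transcripts_with_exon`` lists the transcripts that contain the exon.
    Tissues with zero total expression are skipped with a warning.
    """
    members = [t for t in transcripts_with_exon if t in transcript_tpm.index]
    totals = transcript_tpm.sum(axis=0)
    zero = totals[totals <= 0].index
    if len(zero):
        warnings.warn(
            f"skipping {len(zero)} tissue(s) with zero total expression: "
            f"{', '.join(map(str, zero))}"
        )
    keep = totals[totals > 0].index
    values = transcript_tpm.loc[members, keep].sum(axis=0) / totals[keep]
    return ExonInclusionProfile(
        exon_id=exon_id,
        per_tissue=values,
        mean=float(values.mean()) if len(values) else float("nan"),
        sd=float(values.std(ddof=0)) if len(values) else float("nan"),
    )


def isoform_ratio(
    short_tpm: pd.Series,
    canonical_tpm: pd.Series,
    lo: float = 0.5,
    hi: float = 2.0,
) -> pd.DataFrame:
    """Per-tissue short/canonical expression ratio with an out-of-range flag.

    Tissues with zero canonical expression get NaN ratios (undefined).
    """
    short = short_tpm.astype(float)
    canon = canonical_tpm.astype(float).reindex(short.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = short / canon.where(canon > 0)
    flagged = (ratio < lo) | (ratio > hi)
    return pd.DataFrame(
        {"ratio": ratio, "in_range": ~flagged & ratio.notna(), "flagged": flagged}
    )
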
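"""IP-MS interactome analysis: differential enrichment and NSAF stoichiometry.

Two complementary readouts of an immunoprecipitation mass-spectrometry
experiment:

- *Enrichment* (bait vs control): intensity values are log2-transformed,
  median-centered per run, missing values imputed from a down-shifted
  Gaussian (the standard Perseus-style left-censoring model), then a
  per-protein two-sample t-test with Benjamini-Hochberg adjustment.
- *Stoichiometry*: the normalized spectral abundance factor NSAF — spectral
  counts divided by protein length (SAF), normalized so each run's SAF sum
  to one — is a proxy for molar abundance; expressing every protein's NSAF
  relative to the bait per run, then averaging over replicates, estimates
  complex stoichiometry with the bait fixed at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def compute_nsaf(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Normalized spectral abundance factors, per run.

    SAF = spectral count / protein length (aa); NSAF = SAF / sum of SAF over
    the proteins *detected* in that run, so each run's NSAF column sums to 1
    over detected proteins and zero-count proteins have NSAF exactly 0.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing protein lengths for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("spectral counts must be non-negative")
    zero_runs = counts.columns[arr.sum(axis=0) == 0].tolist()
    if zero_runs:
        raise ValueError(f"run(s) with all-zero counts: {', '.join(map(str, zero_runs))}")
    saf = arr / lengths.to_numpy(dtype=float)[:, None]
    nsaf = saf / saf.sum(axis=0, keepdims=True)
    return pd.DataFrame(nsaf, index=counts.index, columns=counts.columns)


@dataclass
class EnrichmentResult:
    """Per-protein differential-enrichment statistics (bait vs control)."""

    table: pd.DataFrame  # columns: log2fc, p_value, q_value, significant
    fdr: float
    dropped: list[str]

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def enrichment_test(
    quant: pd.DataFrame,
    bait_runs: list[str],
    control_runs: list[str],
    fdr: float = 0.01,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int | None = None,
    welch: bool = True,
    log_transformed: bool = False,
) -> EnrichmentResult:
    """Perseus-style enrichment workflow on an intensity table.

    Pipeline: log2 transform (unless already log scale) -> per-run median
    centering -> imputation of missing values from N(run mean - shift*sd,
    (width*sd)^2) -> two-sample t-test (Welch by default) -> BH adjustment,
    flagging q < ``fdr``.  Proteins absent from every run of both groups
    are dropped with a warning.
    """
    if len(bait_runs) < 2 or len(control_runs) < 2:
        raise ValueError("need at least two runs per group")
    data = quant[list(bait_runs) + list(control_runs)].astype(float)
    if not log_transformed:
        if (data <= 0).any().any():
            raise ValueError("intensities must be positive before log2 transform")
        data = np.log2(data)

    all_missing = data.isna().all(axis=1)
    dropped = data.index[all_missing].tolist()
    if dropped:
        warnings.warn(f"dropping {len(dropped)} protein(s) missing in every run")
        data = data.loc[~all_missing]

    data = data - data.median(axis=0, skipna=True)

    rng = np.random.default_rng(seed)
    for col in data.columns:
        vals = data[col]
        miss = vals.isna()
        if miss.any():
            mu, sd = vals.mean(skipna=True), vals.std(skipna=True, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                sd = 1.0
            data.loc[miss, col] = rng.normal(mu - shift * sd, width * sd, miss.sum())

    bait = data[list(bait_runs)].to_numpy()
    ctrl = data[list(control_runs)].to_numpy()
    log2fc = bait.mean(axis=1) - ctrl.mean(axis=1)
    tt = stats.ttest_ind(bait, ctrl, axis=1, equal_var=not welch)
    pvals = np.where(np.isfinite(tt.pvalue), tt.pvalue, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "significant": qvals < fdr,
        },
        index=data.index,
    )
    return EnrichmentResult(table=table, fdr=fdr, dropped=dropped)


@dataclass
class StoichiometryProfile:
    """Mean bait-relative NSAF ratios with SEM across replicate runs."""

    table: pd.DataFrame  # columns: mean_ratio, sem, n_runs
    bait: str


def stoichiometry(
    nsaf: pd.DataFrame, bait_protein: str, replicate_runs: list[str] | None = None
) -> StoichiometryProfile:
    """Bait-relative stoichiometry from an NSAF table.

    Per run, every protein's NSAF is divided by the bait's NSAF; ratios are
    averaged across replicate runs (SEM = sd/sqrt(n)).  Runs where the bait
    was not detected are excluded with a warning.  The bait's own ratio is
    exactly 1 with SEM 0.
    """
    if bait_protein not in nsaf.index:
        raise ValueError(f"bait {bait_protein!r} not in NSAF table")
    runs = list(replicate_runs) if replicate_runs is not None else list(nsaf.columns)
    bait_vals = nsaf.loc[bait_protein, runs]
    usable = [r for r in runs if bait_vals[r] > 0]
    skipped = sorted(set(runs) - set(usable))
    if skipped:
        warnings.warn(f"bait not detected in run(s) {skipped}; excluded")
    if not usable:
        raise ValueError("bait detected in no replicate run")
    ratios = nsaf[usable].div(nsaf.loc[bait_protein, usable], axis=1)
    n = len(usable)
    mean = ratios.mean(axis=1)
    sem = ratios.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=ratios.index)
    mean.loc[bait_protein] = 1.0
    sem.loc[bait_protein] = 0.0
    table = pd.DataFrame({"mean_ratio": mean, "sem": sem.fillna(0.0), "n_runs": n})
    return StoichiometryProfile(table=table, bait=bait_protein)
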
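"""Covariate (age) correlation analysis of network metrics.

Pearson and Spearman correlations of each global metric with a covariate,
with Benjamini-Hochberg FDR control over the metric family at the
spotlight sparsity and an uncorrected sweep over the full threshold range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass
class CovariateResult:
    metric: str
    sparsity: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    fdr_significant: bool | None = None  # None when uncorrected (sweep rows)
    p_adjusted: float | None = None


def correlate_metric_with_covariate(
    metric_values: np.ndarray,
    covariate_values: np.ndarray,
    metric: str = "",
    sparsity: float = np.nan,
) -> CovariateResult:
    """Two-sided Pearson and Spearman correlations of a metric with a covariate.

    Spearman uses average ranks for ties.  Requires >= 4 paired
    observations and a non-constant covariate; a constant metric is an
    error (correlation undefined).
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric and covariate must be equal-length 1-D arrays")
    if x.size < 4:
        raise ValueError(f"need >= 4 paired observations, got {x.size}")
    if np.std(y) == 0:
        raise ValueError("covariate is constant; correlation undefined")
    if np.std(x) == 0:
        raise ValueError(f"metric {metric or 'values'} constant; correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CovariateResult(
        metric=metric,
        sparsity=sparsity,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=int(x.size),
    )


def bh_fdr(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def sweep_covariate_analysis(
    metric_table: pd.DataFrame,
    covariate: Mapping[str, float] | pd.Series,
    spotlight: float | None = 0.23,
    alpha: float = DEFAULT_ALPHA,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlate every (metric, sparsity) cell with the covariate.

    ``metric_table`` is long-format (subject, sparsity, metric, value).
    FDR correction is applied only to the Pearson p-values of the metric
    family at the spotlight threshold; all other rows carry uncorrected
    flags (``corrected`` column False).
    """
    missing = {"subject", "sparsity", "metric", "value"} - set(metric_table.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    cov = pd.Series(dict(covariate)) if not isinstance(covariate, pd.Series) else covariate
    if metrics is None:
        metrics = sorted(metric_table["metric"].unique())
    thresholds = sorted(np.round(metric_table["sparsity"].unique(), 10))
    rows = []
    for s in thresholds:
        for metric in metrics:
            cell = metric_table[
                (metric_table["metric"] == metric)
                & (np.round(metric_table["sparsity"], 10) == s)
            ].sort_values("subject")
            if cell.empty:
                raise ValueError(f"missing cell for metric={metric}, S={s}")
            subj = cell["subject"].tolist()
            if any(sid not in cov.index for sid in subj):
                raise ValueError("covariate missing for some subjects")
            res = correlate_metric_with_covariate(
                cell["value"].to_numpy(), cov.loc[subj].to_numpy(), metric=metric, sparsity=s
            )
            rows.append(res)
    df = pd.DataFrame(
        {
            "metric": [r.metric for r in rows],
            "sparsity": [r.sparsity for r in rows],
            "n": [r.n for r in rows],
            "pearson_r": [r.pearson_r for r in rows],
            "pearson_p": [r.pearson_p for r in rows],
            "spearman_rho": [r.spearman_rho for r in rows],
            "spearman_p": [r.spearman_p for r in rows],
        }
    )
    df["significant_uncorrected"] = df["pearson_p"] < alpha
    df["corrected"] = False
    df["p_adjusted"] = np.nan
    df["fdr_significant"] = pd.array([pd.NA] * len(df), dtype="boolean")
    if spotlight is not None:
        spot = np.round(df["sparsity"], 10) == round(spotlight, 10)
        if not spot.any():
            raise ValueError(f"spotlight threshold {spotlight} not in the metric table")
        reject, p_adj = bh_fdr(df.loc[spot, "pearson_p"].to_numpy(), alpha=alpha)
        df.loc[spot, "p_adjusted"] = p_adj
        df.loc[spot, "fdr_significant"] = reject
        df.loc[spot, "corrected"] = True
    return df
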
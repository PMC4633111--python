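"""Test-retest reliability via the one-way random-effects ICC.

ICC is the ratio of between-subject variance to total variance,
estimated from a one-way ANOVA: ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW)
for k sessions.  Reliability bands: >= 0.75 excellent, 0.59-0.75 good,
0.40-0.58 fair, below poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from morphnet.similarity import SimilarityMatrix

EXCELLENT_CUTOFF = 0.75


def icc_band(icc: float) -> str:
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.59:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


@dataclass
class ICCResult:
    """One-way random-effects ICC with its variance components."""

    icc: float            # clamped to [0, 1]
    icc_raw: float        # unclamped estimate (can be negative)
    var_between: float
    var_within: float
    f: float
    p: float
    n_subjects: int
    n_sessions: int
    band: str


def _icc_components(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MSB and MSW along axis 0/1 of an (n, k, ...) stack."""
    n, k = x.shape[0], x.shape[1]
    subj_means = x.mean(axis=1)
    grand = subj_means.mean(axis=0)
    msb = k * ((subj_means - grand) ** 2).sum(axis=0) / (n - 1)
    msw = ((x - subj_means[:, np.newaxis]) ** 2).sum(axis=(0, 1)) / (n * (k - 1))
    return msb, msw


def icc_oneway(measurements: np.ndarray) -> ICCResult:
    """ICC(1,1) from a subjects x sessions table (no missing cells).

    Negative raw estimates are clamped to 0 for reporting; the raw value
    is retained.  The p-value is from the one-way ANOVA F test with
    (n-1, n(k-1)) degrees of freedom.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x sessions array")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
    if not np.isfinite(x).all():
        raise ValueError("measurements contain missing or non-finite cells")
    msb, msw = _icc_components(x)
    msb, msw = float(msb), float(msw)
    if msb == 0 and msw == 0:
        raise ValueError("all measurements identical; ICC undefined")
    denom = msb + (k - 1) * msw
    raw = (msb - msw) / denom if denom > 0 else 0.0
    icc = min(max(raw, 0.0), 1.0)
    if msw > 0:
        f = msb / msw
        p = float(stats.f.sf(f, n - 1, n * (k - 1)))
    else:
        f = np.inf
        p = 0.0
    return ICCResult(
        icc=icc,
        icc_raw=raw,
        var_between=max((msb - msw) / k, 0.0),
        var_within=msw,
        f=f,
        p=p,
        n_subjects=n,
        n_sessions=k,
        band=icc_band(icc),
    )


def edge_icc_map(
    session1: Sequence[SimilarityMatrix],
    session2: Sequence[SimilarityMatrix],
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-edge ICC of the raw KLS values across two sessions.

    Returns an R x R ICC matrix (NaN diagonal) and a summary with the
    mean, SD and fraction of edges exceeding the excellent cutoff (0.75).
    """
    if len(session1) != len(session2):
        raise ValueError("sessions have different numbers of subjects")
    ids1 = [m.subject_id for m in session1]
    ids2 = [m.subject_id for m in session2]
    if any(i1 and i2 and i1 != i2 for i1, i2 in zip(ids1, ids2)):
        raise ValueError(f"subject mismatch between sessions: {ids1} vs {ids2}")
    region_ids = session1[0].region_ids
    for m in list(session1) + list(session2):
        if m.region_ids != region_ids:
            raise ValueError("region order differs across matrices")
    n = len(session1)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    x = np.stack(
        [np.stack([s1.entries, s2.entries]) for s1, s2 in zip(session1, session2)]
    )  # (n, 2, R, R)
    r = x.shape[-1]
    diag = np.eye(r, dtype=bool)
    x = np.where(diag, 0.0, x)  # keep the vectorized ANOVA NaN-free
    msb, msw = _icc_components(x)
    denom = msb + (2 - 1) * msw
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom > 0, (msb - msw) / denom, 0.0)
    icc = np.clip(raw, 0.0, 1.0)
    icc[diag] = np.nan
    iu = np.triu_indices(r, k=1)
    vals = icc[iu]
    summary = {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)),
        "fraction_excellent": float(np.mean(vals > EXCELLENT_CUTOFF)),
        "n_edges": int(vals.size),
    }
    return icc, summary


def metric_icc_curve(
    table_session1: pd.DataFrame,
    table_session2: pd.DataFrame,
    metrics: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ICC of each global metric at each sparsity, across two sessions.

    Both tables are long-format with columns (subject, sparsity, metric,
    value) and must cover identical threshold sets.  Returns a long table
    (metric, sparsity, icc, p, band) and a per-metric summary with the
    mean/min/max ICC over the sparsity range.
    """
    for name, t in (("session1", table_session1), ("session2", table_session2)):
        missing = {"subject", "sparsity", "metric", "value"} - set(t.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    s1_thr = set(np.round(table_session1["sparsity"].unique(), 10))
    s2_thr = set(np.round(table_session2["sparsity"].unique(), 10))
    if s1_thr != s2_thr:
        raise ValueError("threshold sets differ between sessions")
    if metrics is None:
        metrics = sorted(set(table_session1["metric"]) & set(table_session2["metric"]))
    rows = []
    for metric in metrics:
        for s in sorted(s1_thr):
            v1 = (
                table_session1[
                    (table_session1["metric"] == metric)
                    & (np.round(table_session1["sparsity"], 10) == s)
                ]
                .sort_values("subject")["value"]
                .to_numpy()
            )
            v2 = (
                table_session2[
                    (table_session2["metric"] == metric)
                    & (np.round(table_session2["sparsity"], 10) == s)
                ]
                .sort_values("subject")["value"]
                .to_numpy()
            )
            if v1.size == 0 or v1.size != v2.size:
                raise ValueError(f"missing or unbalanced cells for metric={metric}, S={s}")
            res = icc_oneway(np.column_stack([v1, v2]))
            rows.append(
                {"metric": metric, "sparsity": s, "icc": res.icc, "p": res.p, "band": res.band}
            )
    curve = pd.DataFrame(rows)
    summary = (
        curve.groupby("metric")["icc"]
        .agg(mean="mean", min="min", max="max")
        .reset_index()
    )
    return curve, summary
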
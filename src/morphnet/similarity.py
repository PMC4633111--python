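"""Symmetric KL divergence and KLS between regional densities.

The edge weight between two regions is ``KLS = exp(-KL(p, q))`` where
``KL`` is the symmetric Kullback-Leibler divergence between the two
regional density estimates, integrated numerically on a shared grid.
KLS lies in [0, 1] and equals 1 for identical distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from morphnet.density import DensityEstimate, GRID_POINTS, estimate_pdf, make_common_grid
from morphnet.volume_io import AtlasParcellation, RegionalSample, VolumeImage, extract_region_samples

#: sentinel stored on the main diagonal — self-connections are excluded
#: from all downstream analyses and must never enter thresholding
DIAGONAL_EXCLUDED = np.nan


def symmetric_kl(p: DensityEstimate, q: DensityEstimate) -> float:
    """Symmetric KL divergence: integral of ``p log(p/q) + q log(q/p)``.

    Both densities must be evaluated on the same grid.  The integral is a
    trapezoid-rule quadrature; the result is non-negative up to numeric
    round-off (tiny negatives are clipped, larger ones are an error).
    """
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("densities must share an evaluation grid")
    integrand = p.density * np.log(p.density / q.density) + q.density * np.log(
        q.density / p.density
    )
    val = float(np.trapezoid(integrand, p.grid))
    if val < -1e-9:
        raise ArithmeticError(f"symmetric KL came out negative ({val}); numeric pathology")
    return max(val, 0.0)


def kls(p: DensityEstimate, q: DensityEstimate) -> float:
    """KL-based similarity ``exp(-KL(p, q))`` in [0, 1]."""
    return float(np.exp(-symmetric_kl(p, q)))


def pair_kls(sample_a: np.ndarray, sample_b: np.ndarray, n_grid: int = GRID_POINTS) -> float:
    """KLS between two raw samples via KDE on their pooled common grid."""
    grid = make_common_grid([sample_a, sample_b], n_points=n_grid)
    return kls(estimate_pdf(sample_a, grid), estimate_pdf(sample_b, grid))


@dataclass
class SimilarityMatrix:
    """R x R matrix of inter-regional KLS values; diagonal is excluded."""

    entries: np.ndarray
    region_ids: list[int]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        r = len(self.region_ids)
        if self.entries.shape != (r, r):
            raise ValueError(
                f"entries shape {self.entries.shape} does not match {r} region ids"
            )
        off = ~np.eye(r, dtype=bool)
        vals = self.entries[off]
        if not np.isfinite(vals).all():
            raise ValueError("off-diagonal entries must be finite")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("KLS values must lie in [0, 1]")
        if not np.allclose(self.entries[off], self.entries.T[off]):
            raise ValueError("similarity matrix must be symmetric")
        np.fill_diagonal(self.entries, DIAGONAL_EXCLUDED)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle values in lexicographic (i, j) pair order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.entries[iu]

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(["region"] + [str(r) for r in self.region_ids])
        lines = [header]
        for rid, row in zip(self.region_ids, self.entries):
            lines.append("\t".join([str(rid)] + [f"{v:.10g}" for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str = "") -> "SimilarityMatrix":
        lines = Path(path).read_text().splitlines()
        region_ids = [int(c) for c in lines[0].split("\t")[1:]]
        rows = [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:] if ln.strip()]
        return cls(entries=np.array(rows), region_ids=region_ids, subject_id=subject_id)


def similarity_from_samples(
    samples: Sequence[RegionalSample],
    subject_id: str = "",
    n_grid: int = GRID_POINTS,
) -> SimilarityMatrix:
    """KLS between all region pairs; each pair uses its own pooled grid."""
    r = len(samples)
    entries = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            try:
                v = pair_kls(samples[i].values, samples[j].values, n_grid=n_grid)
            except ValueError as exc:
                raise ValueError(
                    f"failed on region pair ({samples[i].name or samples[i].region_id}, "
                    f"{samples[j].name or samples[j].region_id}): {exc}"
                ) from exc
            entries[i, j] = entries[j, i] = v
    np.fill_diagonal(entries, DIAGONAL_EXCLUDED)
    return SimilarityMatrix(
        entries=entries,
        region_ids=[s.region_id for s in samples],
        subject_id=subject_id,
    )


def subject_similarity_matrix(
    volume: VolumeImage,
    atlas: AtlasParcellation,
    subject_id: str = "",
    n_grid: int = GRID_POINTS,
) -> SimilarityMatrix:
    """Build one subject's full inter-regional KLS matrix."""
    samples = extract_region_samples(volume, atlas)
    return similarity_from_samples(samples, subject_id=subject_id, n_grid=n_grid)


def _check_cohort(matrices: Sequence[SimilarityMatrix]) -> None:
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    ref = matrices[0].region_ids
    for m in matrices[1:]:
        if m.region_ids != ref:
            raise ValueError("similarity matrices have mismatched region order")


def cohort_mean_matrix(matrices: Sequence[SimilarityMatrix]) -> np.ndarray:
    """Element-wise mean over subjects; the diagonal stays excluded."""
    _check_cohort(matrices)
    stack = np.stack([m.entries for m in matrices])
    mean = stack.mean(axis=0)
    np.fill_diagonal(mean, DIAGONAL_EXCLUDED)
    return mean


def cohort_cv_matrix(matrices: Sequence[SimilarityMatrix]) -> np.ndarray:
    """Element-wise coefficient of variation (sample SD / mean) per edge.

    Edges with zero mean are marked NaN rather than raising.
    """
    _check_cohort(matrices)
    if len(matrices) < 2:
        raise ValueError("CV needs at least 2 subjects")
    stack = np.stack([m.entries for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    np.fill_diagonal(cv, DIAGONAL_EXCLUDED)
    return cv
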
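"""Synthetic atlas-labelled volumes and cohorts for end-to-end testing.

Regions draw voxel intensities from truncated-at-0 normal distributions
with controllable per-region location/scale, per-subject random effects,
session-to-session noise, and a covariate (age) slope on the scale
parameter.  Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from morphnet.volume_io import AtlasParcellation, VolumeImage

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SyntheticSpec:
    """Generator parameters for a synthetic cohort.

    Regions are assigned round-robin to ``n_generator_groups`` generator
    groups; regions in the same group share (mu, sigma) and are the
    "same-generator pairs" a similarity analysis should recover.
    Explicit ``region_mu`` / ``region_sigma`` arrays override the groups.
    """

    shape: tuple[int, int, int] = (30, 30, 30)
    n_regions: int = 90
    voxels_per_region: int = 150
    n_generator_groups: int = 6
    region_mu: np.ndarray | None = None
    region_sigma: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    smoothing_fwhm: float = 0.0
    subject_mu_sd: float = 0.0
    subject_sigma_sd: float = 0.0
    session_noise_sd: float = 0.0
    #: scale multiplier slope; scalar applies to every region, an array of
    #: length n_regions injects region-heterogeneous variance inflation
    covariate_slope: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        if self.voxels_per_region < 2:
            raise ValueError("regions need at least 2 voxels")
        if self.n_regions * self.voxels_per_region > int(np.prod(self.shape)):
            raise ValueError(
                f"{self.n_regions} regions x {self.voxels_per_region} voxels "
                f"do not fit in grid {self.shape}"
            )
        if self.region_mu is None:
            groups = np.arange(self.n_regions) % self.n_generator_groups
            self.region_mu = 0.35 + 0.11 * groups
        else:
            self.region_mu = np.asarray(self.region_mu, dtype=float)
        if self.region_sigma is None:
            groups = np.arange(self.n_regions) % self.n_generator_groups
            self.region_sigma = 0.06 + 0.012 * groups
        else:
            self.region_sigma = np.asarray(self.region_sigma, dtype=float)
        if len(self.region_mu) != self.n_regions or len(self.region_sigma) != self.n_regions:
            raise ValueError("region_mu/region_sigma length must equal n_regions")
        if (self.region_sigma <= 0).any():
            raise ValueError("all region scales must be positive")
        slope = np.asarray(self.covariate_slope, dtype=float)
        if slope.ndim == 0:
            slope = np.full(self.n_regions, float(slope))
        elif slope.shape != (self.n_regions,):
            raise ValueError("covariate_slope must be a scalar or length-n_regions array")
        self._slope_per_region = slope

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, self.n_regions + 1))

    def same_generator_pairs(self) -> list[tuple[int, int]]:
        """Region-id pairs drawn from identical (mu, sigma) generators."""
        params = list(zip(self.region_mu.tolist(), self.region_sigma.tolist()))
        pairs = []
        for i in range(self.n_regions):
            for j in range(i + 1, self.n_regions):
                if params[i] == params[j]:
                    pairs.append((i + 1, j + 1))
        return pairs


def generate_atlas(spec: SyntheticSpec) -> AtlasParcellation:
    """Deterministic parcellation: contiguous voxel blocks per region.

    Block placement order is a seeded permutation of the regions, so the
    layout depends only on the master seed.
    """
    labels = np.zeros(int(np.prod(spec.shape)), dtype=np.int32)
    order = np.random.default_rng((spec.seed, 7)).permutation(spec.n_regions)
    offset = 0
    for r in order:
        labels[offset : offset + spec.voxels_per_region] = r + 1
        offset += spec.voxels_per_region
    affine = np.diag(list(spec.voxel_size) + [1.0])
    return AtlasParcellation(
        labels=labels.reshape(spec.shape),
        region_ids=spec.region_ids,
        region_names={r: f"R{r:03d}" for r in spec.region_ids},
        voxel_size=spec.voxel_size,
        affine=affine,
    )


def _subject_effects(spec: SyntheticSpec, subject_index: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng((spec.seed, 101, subject_index))
    u_mu = rng.normal(0.0, spec.subject_mu_sd, size=spec.n_regions) if spec.subject_mu_sd else np.zeros(spec.n_regions)
    u_sigma = (
        rng.normal(0.0, spec.subject_sigma_sd, size=spec.n_regions)
        if spec.subject_sigma_sd
        else np.zeros(spec.n_regions)
    )
    return u_mu, u_sigma


def generate_subject(
    spec: SyntheticSpec,
    atlas: AtlasParcellation,
    subject_index: int,
    covariate: float = 0.0,
    session: int = 1,
) -> VolumeImage:
    """One subject/session volume.

    Region r's voxels are drawn from a truncated-at-0 normal with
    location ``mu_r + u_mr`` and scale
    ``sigma_r * (1 + slope * covariate) + u_sigma_mr + w_mrs`` where the
    ``u`` terms are subject random effects (shared across sessions) and
    ``w`` is per-session noise.  Voxel-level randomness is seeded by
    (master seed, subject) only, so zero session noise reproduces the
    session-1 volume exactly.
    """
    u_mu, u_sigma = _subject_effects(spec, subject_index)
    voxel_rng = np.random.default_rng((spec.seed, 303, subject_index))
    session_rng = np.random.default_rng((spec.seed, 202, subject_index, session))
    w = (
        session_rng.normal(0.0, spec.session_noise_sd, size=spec.n_regions)
        if spec.session_noise_sd
        else np.zeros(spec.n_regions)
    )
    values = np.zeros(spec.shape, dtype=float)
    for idx, r in enumerate(spec.region_ids):
        mask = atlas.labels == r
        n_vox = int(mask.sum())
        loc = spec.region_mu[idx] + u_mu[idx]
        scale = spec.region_sigma[idx] * (1.0 + spec._slope_per_region[idx] * covariate)
        scale = scale + u_sigma[idx] + w[idx]
        if scale <= 0:
            raise ValueError(
                f"effective scale for region {r} is {scale:.4g} <= 0; "
                "reduce effect/noise SDs or the covariate slope"
            )
        u = voxel_rng.random(n_vox)
        a = (0.0 - loc) / scale
        values[mask] = stats.truncnorm.ppf(u, a, np.inf, loc=loc, scale=scale)
    if spec.smoothing_fwhm > 0:
        sigma_vox = [
            spec.smoothing_fwhm / _FWHM_TO_SD / vs for vs in spec.voxel_size
        ]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
        values = np.maximum(values, 0.0)
    return VolumeImage(values=values, voxel_size=spec.voxel_size, affine=atlas.affine)


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its provenance manifest."""

    spec: SyntheticSpec
    atlas: AtlasParcellation
    volumes: dict[tuple[str, int], VolumeImage]
    covariates: dict[str, float]
    subject_ids: list[str]
    n_sessions: int
    manifest: dict = field(default_factory=dict)


def generate_cohort(
    spec: SyntheticSpec,
    n_subjects: int,
    covariates: Sequence[float] | None = None,
    n_sessions: int = 1,
    subject_ids: Sequence[str] | None = None,
    outdir: str | Path | None = None,
) -> Cohort:
    """Generate a full cohort (optionally two sessions), with manifest.

    When ``outdir`` is given, volumes and atlas are written as NIfTI and
    the manifest (seeds, true generating parameters, same-generator
    pairs) as JSON, so the cohort is reproducible and recoverable from
    disk alone.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if covariates is None:
        covariates = [0.0] * n_subjects
    if len(covariates) != n_subjects:
        raise ValueError("covariates length must equal n_subjects")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(n_subjects)]
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    atlas = generate_atlas(spec)
    volumes: dict[tuple[str, int], VolumeImage] = {}
    for i, sid in enumerate(subject_ids):
        for ses in range(1, n_sessions + 1):
            volumes[(sid, ses)] = generate_subject(
                spec, atlas, subject_index=i, covariate=float(covariates[i]), session=ses
            )
    manifest = {
        "seed": spec.seed,
        "n_subjects": n_subjects,
        "n_sessions": n_sessions,
        "subject_ids": subject_ids,
        "covariates": {sid: float(c) for sid, c in zip(subject_ids, covariates)},
        "shape": list(spec.shape),
        "n_regions": spec.n_regions,
        "voxels_per_region": spec.voxels_per_region,
        "region_mu": spec.region_mu.tolist(),
        "region_sigma": spec.region_sigma.tolist(),
        "subject_mu_sd": spec.subject_mu_sd,
        "subject_sigma_sd": spec.subject_sigma_sd,
        "session_noise_sd": spec.session_noise_sd,
        "covariate_slope": spec._slope_per_region.tolist(),
        "smoothing_fwhm": spec.smoothing_fwhm,
        "same_generator_pairs": [list(p) for p in spec.same_generator_pairs()],
    }
    cohort = Cohort(
        spec=spec,
        atlas=atlas,
        volumes=volumes,
        covariates={sid: float(c) for sid, c in zip(subject_ids, covariates)},
        subject_ids=subject_ids,
        n_sessions=n_sessions,
        manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        atlas.save(outdir / "atlas.nii")
        files = {}
        for (sid, ses), vol in volumes.items():
            fname = f"{sid}_ses-{ses}.nii"
            vol.save(outdir / fname)
            files[f"{sid}_ses-{ses}"] = fname
        with open(outdir / "regions.tsv", "w") as fh:
            fh.write("id\tname\themisphere\n")
            for r in spec.region_ids:
                fh.write(f"{r}\tR{r:03d}\t{'L' if r % 2 else 'R'}\n")
        manifest["files"] = files
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohort
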
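"""End-to-end orchestration: volumes -> similarity -> graphs -> analyses.

A single RunConfig drives the whole workflow: per-subject similarity
matrices, adjacency matrices and metrics across the sparsity sweep,
cohort mean/CV maps, hub identification and betweenness-profile scores,
plus optional test-retest reliability (two sessions) and covariate
correlation analyses.  All randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import morphnet
from morphnet.reliability import edge_icc_map, metric_icc_curve
from morphnet.similarity import (
    SimilarityMatrix,
    cohort_cv_matrix,
    cohort_mean_matrix,
    subject_similarity_matrix,
)
from morphnet.network import (
    GLOBAL_METRIC_NAMES,
    binarize_by_sparsity,
    betweenness_normalized,
    identify_hubs,
    profile_similarity_uniqueness,
    small_world_metrics,
)
from morphnet.stats_analysis import sweep_covariate_analysis
from morphnet.synthetic_data import Cohort, SyntheticSpec, generate_cohort
from morphnet.volume_io import load_atlas, load_gm_volume, refine_atlas

log = logging.getLogger("morphnet")

DEFAULT_SPARSITIES = tuple(np.round(np.arange(0.10, 0.401, 0.01), 2).tolist())


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    output_dir: str = "morphnet_out"
    # either a synthetic block ...
    synthetic: dict | None = None
    n_subjects: int = 0
    n_sessions: int = 1
    covariates: dict[str, float] | list[float] | None = None
    # ... or real inputs
    volumes: dict[str, list[str]] | None = None  # subject id -> [session paths]
    atlas_path: str | None = None
    region_table: str | None = None
    refine: bool = True
    gm_threshold: float = 0.0
    neighborhood_mm: float = 2.0
    # analysis settings
    sparsities: Sequence[float] = field(default_factory=lambda: list(DEFAULT_SPARSITIES))
    spotlight: float = 0.23
    n_random: int = 100
    seed: int = 0
    write_adjacency: bool = True

    def __post_init__(self) -> None:
        s = [round(float(v), 10) for v in self.sparsities]
        if len(set(s)) != len(s) or any(not 0 < v < 1 for v in s):
            raise ValueError("sparsities must be unique values in (0, 1)")
        self.sparsities = sorted(s)
        if self.spotlight is not None and round(self.spotlight, 10) not in self.sparsities:
            raise ValueError(f"spotlight {self.spotlight} must be one of the sparsities")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)


def _load_cohort(config: RunConfig) -> Cohort:
    if config.synthetic is not None:
        spec = SyntheticSpec(seed=config.seed, **config.synthetic)
        cov = config.covariates
        if isinstance(cov, dict):
            cov = list(cov.values())
        cohort = generate_cohort(
            spec,
            n_subjects=config.n_subjects,
            covariates=cov,
            n_sessions=config.n_sessions,
        )
        if config.covariates is None:
            cohort.covariates = {}  # no covariate analysis requested
        return cohort
    if not config.volumes or not config.atlas_path or not config.region_table:
        raise ValueError("config needs either a synthetic block or volumes+atlas+region_table")
    subject_ids = sorted(config.volumes)
    n_sessions = len(next(iter(config.volumes.values())))
    vols = {}
    reference = None
    for sid in subject_ids:
        paths = config.volumes[sid]
        if len(paths) != n_sessions:
            raise ValueError(f"subject {sid} has {len(paths)} sessions, expected {n_sessions}")
        for ses, p in enumerate(paths, start=1):
            vols[(sid, ses)] = load_gm_volume(p)
            reference = vols[(sid, ses)]
    atlas = load_atlas(config.atlas_path, config.region_table, reference=reference)
    covariates = config.covariates if isinstance(config.covariates, dict) else {}
    spec = SyntheticSpec(
        shape=atlas.shape,
        n_regions=atlas.n_regions,
        voxels_per_region=2,
        n_generator_groups=1,
        region_mu=np.zeros(atlas.n_regions) + 1,
        region_sigma=np.ones(atlas.n_regions),
        seed=config.seed,
    )
    return Cohort(
        spec=spec,
        atlas=atlas,
        volumes=vols,
        covariates={sid: float(covariates.get(sid, np.nan)) for sid in subject_ids},
        subject_ids=subject_ids,
        n_sessions=n_sessions,
        manifest={"subject_ids": subject_ids, "n_sessions": n_sessions},
    )


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_full_pipeline(config: RunConfig) -> Path:
    """Run the complete workflow and return the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_seen: list[str] = []

    t0 = _stage("load/generate cohort")
    cohort = _load_cohort(config)
    atlas = cohort.atlas
    if config.synthetic is None and config.refine:
        any_vol = next(iter(cohort.volumes.values()))
        atlas, removed = refine_atlas(
            atlas, any_vol, gm_threshold=config.gm_threshold, neighborhood_mm=config.neighborhood_mm
        )
        log.info("atlas refinement removed %d voxels", sum(removed.values()))
    timings["cohort"] = time.perf_counter() - t0

    t0 = _stage("similarity matrices")
    sims: dict[tuple[str, int], SimilarityMatrix] = {}
    simdir = out / "similarity"
    simdir.mkdir(exist_ok=True)
    for sid in cohort.subject_ids:
        for ses in range(1, cohort.n_sessions + 1):
            try:
                sm = subject_similarity_matrix(
                    cohort.volumes[(sid, ses)], atlas, subject_id=sid
                )
            except Exception as exc:
                raise RuntimeError(
                    f"similarity stage failed for subject {sid}, session {ses}: {exc}"
                ) from exc
            sims[(sid, ses)] = sm
            sm.to_tsv(simdir / f"{sid}_ses-{ses}_kls.tsv")
    timings["similarity"] = time.perf_counter() - t0

    t0 = _stage("cohort mean/CV maps")
    session1 = [sims[(sid, 1)] for sid in cohort.subject_ids]
    mean_mat = cohort_mean_matrix(session1)
    _write_matrix(out / "cohort_mean_kls.tsv", mean_mat, atlas.region_ids)
    if len(session1) >= 2:
        cv_mat = cohort_cv_matrix(session1)
        _write_matrix(out / "cohort_cv_kls.tsv", cv_mat, atlas.region_ids)
    timings["cohort_maps"] = time.perf_counter() - t0

    t0 = _stage("binarization + graph metrics")
    metric_rows = []
    betweenness_profiles: dict[int, dict[str, np.ndarray]] = {}
    adjdir = out / "adjacency"
    if config.write_adjacency:
        adjdir.mkdir(exist_ok=True)
    rows_spotlight_b = {}
    for (sid, ses), sm in sims.items():
        for s in config.sparsities:
            adj = binarize_by_sparsity(sm, s)
            if config.write_adjacency and ses == 1:
                _write_edgelist(adjdir / f"{sid}_S{int(round(s * 100)):02d}.tsv", adj)
            gm = small_world_metrics(adj, n_random=config.n_random, seed=_net_seed(config.seed, sid, ses, s))
            if not gm.connected:
                warnings_seen.append(f"disconnected graph: subject {sid} ses {ses} S={s}")
            for metric, value in gm.as_dict().items():
                metric_rows.append(
                    {"subject": sid, "session": ses, "sparsity": s, "metric": metric, "value": value}
                )
            if round(s, 10) == round(config.spotlight, 10) and ses == 1:
                nodal = betweenness_normalized(adj)
                rows_spotlight_b[sid] = nodal.normalized_betweenness
    metric_table = pd.DataFrame(metric_rows)
    metric_table.to_csv(out / "metrics_long.tsv", sep="\t", index=False)
    timings["metrics"] = time.perf_counter() - t0

    t0 = _stage("hubs + profile scores")
    b_stack = np.vstack([rows_spotlight_b[sid] for sid in cohort.subject_ids])
    hubs, mean_b, threshold = identify_hubs(b_stack, region_ids=atlas.region_ids)
    hub_df = pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "region_name": [atlas.region_names.get(r, str(r)) for r in atlas.region_ids],
            "mean_normalized_betweenness": mean_b,
            "is_hub": [r in hubs for r in atlas.region_ids],
        }
    )
    hub_df.to_csv(out / "hubs.tsv", sep="\t", index=False)
    if len(cohort.subject_ids) >= 2:
        scores = profile_similarity_uniqueness(b_stack)
        pd.DataFrame(
            {
                "subject": cohort.subject_ids,
                "similarity_raw": scores.similarity_raw,
                "uniqueness_raw": scores.uniqueness_raw,
                "similarity": scores.similarity,
                "uniqueness": scores.uniqueness,
            }
        ).to_csv(out / "profile_scores.tsv", sep="\t", index=False)
    timings["hubs"] = time.perf_counter() - t0

    if cohort.n_sessions >= 2:
        t0 = _stage("test-retest reliability")
        ses1 = [sims[(sid, 1)] for sid in cohort.subject_ids]
        ses2 = [sims[(sid, 2)] for sid in cohort.subject_ids]
        icc_mat, summary = edge_icc_map(ses1, ses2)
        _write_matrix(out / "edge_icc.tsv", icc_mat, atlas.region_ids)
        (out / "edge_icc_summary.json").write_text(json.dumps(summary, indent=2))
        t1 = metric_table[metric_table["session"] == 1]
        t2 = metric_table[metric_table["session"] == 2]
        curve, curve_summary = metric_icc_curve(t1, t2)
        curve.to_csv(out / "metric_icc_curve.tsv", sep="\t", index=False)
        curve_summary.to_csv(out / "metric_icc_summary.tsv", sep="\t", index=False)
        timings["reliability"] = time.perf_counter() - t0

    have_cov = cohort.covariates and all(np.isfinite(list(cohort.covariates.values())))
    if have_cov:
        t0 = _stage("covariate analysis")
        t1 = metric_table[metric_table["session"] == 1]
        cov_df = sweep_covariate_analysis(
            t1, cohort.covariates, spotlight=config.spotlight
        )
        cov_df.to_csv(out / "covariate_analysis.tsv", sep="\t", index=False)
        timings["covariate"] = time.perf_counter() - t0

    manifest = {
        "morphnet_version": morphnet.__version__,
        "seed": config.seed,
        "sparsities": list(config.sparsities),
        "spotlight": config.spotlight,
        "n_random": config.n_random,
        "n_subjects": len(cohort.subject_ids),
        "n_sessions": cohort.n_sessions,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "warnings": warnings_seen,
        "cohort": cohort.manifest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("pipeline finished: %s", out)
    return out


def _net_seed(seed: int, sid: str, ses: int, s: float) -> int:
    # stable per-(subject, session, threshold) seed for the null ensemble
    # (zlib.crc32 is process-stable, unlike built-in str hashing)
    return int(
        np.random.SeedSequence(
            [seed, zlib.crc32(sid.encode()), ses, int(round(s * 1000))]
        ).generate_state(1)[0]
    )


def _write_matrix(path: Path, matrix: np.ndarray, region_ids: Sequence[int]) -> None:
    header = "\t".join(["region"] + [str(r) for r in region_ids])
    lines = [header]
    for rid, row in zip(region_ids, matrix):
        lines.append("\t".join([str(rid)] + [f"{v:.10g}" for v in row]))
    path.write_text("\n".join(lines) + "\n")


def _write_edgelist(path: Path, adj) -> None:
    lines = ["region_i\tregion_j"]
    ids = adj.region_ids
    for i, j in adj.edge_list():
        lines.append(f"{ids[i]}\t{ids[j]}")
    path.write_text("\n".join(lines) + "\n")
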
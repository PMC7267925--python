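"""Config-driven orchestration: denoise -> connectivity -> group stats and
outcome prediction, with provenance and per-stage seeding.

The in-memory entry point is :func:`process_cohort`; :func:`run_pipeline`
adds file I/O around it from a validated :class:`PipelineConfig`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, confounds, connectivity, denoise, group_stats, prediction
from .volumes import (
    BoldRun,
    MaskSet,
    MotionTrace,
    read_bold,
    read_masks,
    read_motion,
    read_subjects,
    write_cluster_table,
    write_json,
    write_map,
)

__all__ = [
    "PipelineConfig",
    "PipelineOptions",
    "stage_seed",
    "validate_config",
    "process_cohort",
    "run_pipeline",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed by hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class PipelineOptions:
    """Analysis knobs shared by the file-based and in-memory entry points."""

    strategy: str = "acompcor"
    denoise_params: denoise.DenoiseParams = field(default_factory=denoise.DenoiseParams)
    outlier_percentile: float = 97.0
    seed_spec: connectivity.SeedSpec = field(default_factory=connectivity.SeedSpec)
    gbc_exponent: str = "squared"
    feature_kinds: tuple[str, ...] = ("gbc", "seed_fc_z")
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_alphas: int = 20
    n_perm_prediction: int = 1000
    n_perm_group: int = 1000
    perm_reuse_hyperparams: bool = False
    min_cluster_voxels: int = 100
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    run_group_stats: bool = True
    run_baseline_control: bool = True
    rng_seed: int = 0
    voxel_size_mm: float = 3.0


def process_cohort(
    runs: list[BoldRun],
    masks: MaskSet,
    motions: list[MotionTrace],
    subjects: pd.DataFrame,
    options: PipelineOptions,
) -> dict:
    """Run the full analysis on an in-memory cohort.

    Per subject: outlier detection and confound assembly from the
    unsmoothed run, spatial smoothing, the temporal denoising chain, then
    GBC and seed-FC maps.  Group t-map + cluster FWE on the seed-FC maps,
    and LOOCV elastic-net prediction (with permutation inference and the
    baseline-score specificity control) per feature kind.
    """
    subjects = subjects.reset_index(drop=True).copy()
    if not (len(runs) == len(motions) == len(subjects)):
        raise ValueError("runs, motions and subjects table lengths differ")

    gbc_maps, fc_maps, logs = [], [], []
    mean_fds = []
    for run, motion in zip(runs, motions):
        outliers = confounds.detect_outliers(
            run, motion, percentile=options.outlier_percentile, brain_mask=masks.brain)
        model = confounds.assemble_confounds(
            motion, outliers, run, masks, strategy=options.strategy)
        smoothed = denoise.smooth_gaussian(
            run, options.denoise_params.smoothing_fwhm_mm, options.voxel_size_mm)
        cleaned, stage_log = denoise.run_denoise_chain(
            smoothed, model, options.denoise_params)
        gbc_maps.append(connectivity.gbc_map(
            cleaned, masks.brain, exponent=options.gbc_exponent))
        seed_series = connectivity.seed_timeseries(cleaned, options.seed_spec, masks.brain)
        fc_maps.append(connectivity.seed_fc_map(cleaned, seed_series, masks.brain))
        mean_fds.append(confounds.mean_fd(motion))
        logs.append({"subject_id": run.subject_id, "n_outliers": int(outliers.flags.sum()),
                     "n_confound_columns": model.n_columns, "stages": stage_log})

    subjects["mean_fd"] = mean_fds
    subjects["hdrs_pct_change"] = [
        clinical.pct_change(b, p)
        for b, p in zip(subjects["hdrs_baseline"], subjects["hdrs_post"])
    ]

    results: dict = {
        "subjects": subjects,
        "maps": {"gbc": gbc_maps, "seed_fc_z": fc_maps},
        "logs": logs,
        "predictions": {},
        "baseline_controls": {},
    }

    if options.run_group_stats:
        design = group_stats.GroupDesign(
            n_subjects=len(subjects),
            covariates=subjects[["age", "sex", "mean_fd"]])
        t_map = group_stats.one_sample_t_map(fc_maps, design)
        cluster_table = group_stats.cluster_fwe(
            fc_maps, design, voxel_p=options.voxel_p, cluster_alpha=options.cluster_alpha,
            n_perm=options.n_perm_group, rng_seed=stage_seed(options.rng_seed, "group"))
        results["group"] = {"t_map": t_map, "clusters": cluster_table}

    for kind in options.feature_kinds:
        spec = prediction.PredictionSpec(
            feature_kind=kind,
            l1_ratios=options.l1_ratios,
            n_alphas=options.n_alphas,
            n_perm=options.n_perm_prediction,
            min_cluster_voxels=options.min_cluster_voxels,
            rng_seed=stage_seed(options.rng_seed, f"predict:{kind}"),
            perm_reuse_hyperparams=options.perm_reuse_hyperparams,
        )
        results["predictions"][kind] = prediction.loocv_predict(
            results["maps"][kind], subjects, spec)
        if options.run_baseline_control:
            results["baseline_controls"][kind] = prediction.baseline_control(
                results["maps"][kind], subjects, spec)
    return results


@dataclass
class PipelineConfig:
    """Paths + options, typically parsed from a YAML tree."""

    bold_paths: list[str]
    motion_paths: list[str]
    brain_mask: str
    gm_mask: str
    wm_mask: str
    csf_mask: str
    subjects_table: str
    output_dir: str
    tr_seconds: float = 2.0
    options: PipelineOptions = field(default_factory=PipelineOptions)

    @classmethod
    def from_dict(cls, tree: dict) -> "PipelineConfig":
        paths = tree.get("paths", {})
        opts_tree = {k: v for k, v in tree.items() if k != "paths"}
        options = PipelineOptions()
        denoise_tree = opts_tree.pop("denoise", {})
        strategy = denoise_tree.pop("strategy", None)
        if strategy:
            options.strategy = strategy
        if denoise_tree:
            options.denoise_params = denoise.DenoiseParams(**denoise_tree)
        conn_tree = opts_tree.pop("connectivity", {})
        if "seed_mm" in conn_tree or "seed_diameter_mm" in conn_tree:
            options.seed_spec = connectivity.SeedSpec(
                center_mm=tuple(conn_tree.get("seed_mm", (0.0, 38.0, 4.0))),
                diameter_mm=conn_tree.get("seed_diameter_mm", 6.0))
        if "gbc_exponent" in conn_tree:
            options.gbc_exponent = conn_tree["gbc_exponent"]
        pred_tree = opts_tree.pop("prediction", {})
        for key in ("l1_ratios", "n_alphas", "min_cluster_voxels",
                    "perm_reuse_hyperparams"):
            if key in pred_tree:
                setattr(options, key,
                        tuple(pred_tree[key]) if key == "l1_ratios" else pred_tree[key])
        if "n_perm" in pred_tree:
            options.n_perm_prediction = pred_tree["n_perm"]
        group_tree = opts_tree.pop("group", {})
        for key in ("voxel_p", "cluster_alpha"):
            if key in group_tree:
                setattr(options, key, group_tree[key])
        if "n_perm" in group_tree:
            options.n_perm_group = group_tree["n_perm"]
        for key in ("rng_seed", "voxel_size_mm"):
            if key in opts_tree:
                setattr(options, key, opts_tree[key])
        return cls(
            bold_paths=list(paths.get("bold", [])),
            motion_paths=list(paths.get("motion", [])),
            brain_mask=paths.get("brain_mask", ""),
            gm_mask=paths.get("gm_mask", ""),
            wm_mask=paths.get("wm_mask", ""),
            csf_mask=paths.get("csf_mask", ""),
            subjects_table=paths.get("subjects", ""),
            output_dir=paths.get("output_dir", "out"),
            tr_seconds=opts_tree.get("tr_seconds", 2.0),
            options=options,
        )


def validate_config(config: PipelineConfig) -> list[dict]:
    """Static checks: paths exist, counts align, band fits under Nyquist."""
    findings: list[dict] = []

    def err(msg: str) -> None:
        findings.append({"severity": "error", "message": msg})

    if len(config.bold_paths) != len(config.motion_paths):
        err(f"{len(config.bold_paths)} BOLD runs but {len(config.motion_paths)} motion files")
    for label, path in [("bold", p) for p in config.bold_paths] + \
                       [("motion", p) for p in config.motion_paths] + \
                       [("brain_mask", config.brain_mask), ("gm_mask", config.gm_mask),
                        ("wm_mask", config.wm_mask), ("csf_mask", config.csf_mask),
                        ("subjects", config.subjects_table)]:
        if not path or not Path(path).exists():
            err(f"missing {label} file: {path!r}")
    try:
        config.options.denoise_params.validate(config.tr_seconds)
    except ValueError as exc:
        err(str(exc))
    return findings


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline run; writes maps, tables, prediction JSONs, provenance."""
    findings = validate_config(config)
    errors = [f for f in findings if f["severity"] == "error"]
    if errors:
        raise ValueError("config validation failed: "
                         + "; ".join(f["message"] for f in errors))

    subjects = read_subjects(config.subjects_table)
    runs, motions = [], []
    for (_, row), bold_path, motion_path in zip(
            subjects.iterrows(), config.bold_paths, config.motion_paths):
        sid = str(row["subject_id"])
        try:
            runs.append(read_bold(bold_path, config.tr_seconds, subject_id=sid))
            motions.append(read_motion(motion_path, subject_id=sid))
        except Exception as exc:
            raise RuntimeError(f"stage=load subject={sid}: {exc}") from exc
    masks = read_masks(config.brain_mask, config.gm_mask, config.wm_mask, config.csf_mask)

    started = time.time()
    results = process_cohort(runs, masks, motions, subjects, config.options)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for kind, maps in results["maps"].items():
        for m in maps:
            write_map(m, out_dir / f"{m.subject_id}_{kind}.nii")
    if "group" in results:
        write_map(results["group"]["t_map"], out_dir / "group_seed_fc_t.nii")
        write_cluster_table(results["group"]["clusters"], out_dir / "group_clusters.tsv")
    for kind, res in results["predictions"].items():
        write_json(res.to_dict(), out_dir / f"prediction_{kind}.json")
        write_map(res.weight_map, out_dir / f"weights_{kind}.nii")
        write_cluster_table(res.cluster_table, out_dir / f"weights_{kind}_clusters.tsv")
    for kind, res in results["baseline_controls"].items():
        write_json(res.to_dict(), out_dir / f"baseline_control_{kind}.json")
    write_json({
        "config_hash": _config_hash(config),
        "rng_seed": config.options.rng_seed,
        "strategy": config.options.strategy,
        "elapsed_seconds": round(time.time() - started, 3),
        "stage_logs": results["logs"],
    }, out_dir / "provenance.json")
    return results
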
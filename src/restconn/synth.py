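"""Synthetic resting-state cohorts with a known connectivity->outcome coupling.

Each cohort plants: a band-limited (0.01-0.1 Hz) latent signal shared by a
spherical "seed" region, target regions coupled to it with per-subject
strength beta_s, compartment-specific WM/CSF nuisance signals that leak
weakly into gray matter, per-voxel drifts, bounded random-walk motion with
injected spike frames (global intensity jump + motion step), and an
integer-consistent clinical outcome linearly driven by beta_s.  Everything
is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import (
    BoldRun,
    MaskSet,
    MotionTrace,
    write_bold,
    write_mask,
    write_motion,
    write_subjects,
)

__all__ = ["SynthConfig", "SynthTruth", "generate_cohort", "write_cohort"]

HDRS_MAX = 52


@dataclass
class SynthConfig:
    grid_shape: tuple[int, int, int] = (20, 20, 14)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    n_subjects: int = 22
    seed_center_mm: tuple[float, float, float] = (0.0, 15.0, 3.0)
    target_centers_mm: tuple = ((0.0, -15.0, 3.0), (12.0, 12.0, -3.0))
    region_radius_mm: float = 6.0
    coupling_mean: float = 0.8
    coupling_sd: float = 0.35
    outcome_slope: float = 0.5
    outcome_noise_sd: float = 0.05
    covariate_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spike_rate: float = 0.015
    spike_amplitude_sd_units: float = 6.0
    drift_amplitude: float = 1.0
    rng_seed: int = 0
    # signal-scale plumbing (SD units of the voxel noise)
    signal_amplitude: float = 1.0
    voxel_noise_sd: float = 1.0
    nuisance_amplitude: float = 1.5
    leak_weight: float = 0.12
    baseline_intensity: float = 100.0
    band_low_hz: float = 0.015
    band_high_hz: float = 0.09
    intended_band_low_hz: float | None = None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or any(v < 4 for v in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: every axis needs >= 4 voxels")
        if self.voxel_size_mm <= 0 or self.tr_seconds <= 0:
            raise ValueError("voxel size and TR must be positive")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.coupling_sd < 0:
            raise ValueError("coupling_sd must be >= 0")
        if not 0.0 <= self.spike_rate <= 0.2:
            raise ValueError("spike_rate must lie in [0, 0.2]")
        if self.spike_amplitude_sd_units <= 0:
            raise ValueError("spike_amplitude_sd_units must be positive")
        if self.outcome_noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise/drift amplitudes must be >= 0")
        if self.region_radius_mm <= 0:
            raise ValueError("region_radius_mm must be positive")
        if self.intended_band_low_hz is not None:
            duration = self.n_timepoints * self.tr_seconds
            if duration < 10.0 / self.intended_band_low_hz:
                warnings.warn(
                    f"run duration {duration:.0f}s gives fewer than 10 cycles at "
                    f"{self.intended_band_low_hz} Hz", stacklevel=2)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        offset = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        aff[:3, 3] = offset
        return aff


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort."""

    beta: np.ndarray                       # per-subject seed->target coupling
    spike_indices: list[np.ndarray]        # per-subject injected spike frames
    noiseless_outcome: np.ndarray          # slope*beta + covariate terms
    seed_mask: np.ndarray = None
    target_mask: np.ndarray = None
    latent_signals: np.ndarray = None      # (n_subjects, t) planted seed signals


def _world_grid(config: SynthConfig) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in config.grid_shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(np.float64)
    aff = config.affine
    return idx @ aff[:3, :3].T + aff[:3, 3]


def _ellipsoid(world: np.ndarray, center, semi_axes) -> np.ndarray:
    d = (world - np.asarray(center, dtype=np.float64)) / np.asarray(semi_axes, np.float64)
    return (d**2).sum(axis=-1) <= 1.0


def make_masks(config: SynthConfig) -> MaskSet:
    """Ellipsoidal brain with disjoint interior WM and CSF compartments."""
    world = _world_grid(config)
    half_extent = np.asarray(config.grid_shape) * config.voxel_size_mm / 2.0
    brain_semi = 0.85 * half_extent
    brain = _ellipsoid(world, (0, 0, 0), brain_semi)
    wm = _ellipsoid(world, (-0.35 * brain_semi[0], 0, 0), 0.28 * brain_semi) & brain
    csf = _ellipsoid(world, (0.35 * brain_semi[0], 0, 0), 0.22 * brain_semi) & brain
    csf &= ~wm
    gm = brain & ~wm & ~csf
    return MaskSet(brain=brain, gm=gm, wm=wm, csf=csf, affine=config.affine)


def _region_sphere(config: SynthConfig, world: np.ndarray, center) -> np.ndarray:
    d2 = ((world - np.asarray(center, dtype=np.float64)) ** 2).sum(axis=-1)
    return d2 <= config.region_radius_mm**2 + 1e-9


def _band_limited_signal(rng: np.random.Generator, config: SynthConfig,
                         n_components: int = 8) -> np.ndarray:
    """Unit-SD sum of sinusoids with frequencies inside the pass band."""
    t = np.arange(config.n_timepoints) * config.tr_seconds
    freqs = rng.uniform(config.band_low_hz, config.band_high_hz, n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    amps = rng.uniform(0.5, 1.0, n_components)
    sig = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None] + phases[:, None])
           ).sum(axis=0)
    return sig / sig.std()


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _motion_trace(rng: np.random.Generator, config: SynthConfig,
                  spikes: np.ndarray) -> MotionTrace:
    t = config.n_timepoints
    steps = np.column_stack([rng.normal(0, 0.02, (t, 3)), rng.normal(0, 4e-4, (t, 3))])
    steps[0] = 0.0
    for frame in spikes:
        axis_t = rng.integers(0, 3)
        axis_r = rng.integers(3, 6)
        steps[frame, axis_t] += rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.2)
        steps[frame, axis_r] += rng.choice([-1.0, 1.0]) * 0.01
    walk = np.cumsum(steps, axis=0)
    walk[:, :3] = np.clip(walk[:, :3], -2.0, 2.0)
    walk[:, 3:] = np.clip(walk[:, 3:], -0.04, 0.04)
    return MotionTrace(params=walk)


def generate_cohort(config: SynthConfig):
    """Generate (runs, masks, motions, subjects table, truth) from config.

    See the module docstring for the planted structure.  The subjects table
    carries integer HDRS baseline/post scores whose exact percent change
    (baseline - post) / baseline is the quantized planted outcome.
    """
    rng = np.random.default_rng(config.rng_seed)
    masks = make_masks(config)
    world = _world_grid(config)

    seed_region = _region_sphere(config, world, config.seed_center_mm) & masks.gm
    target_region = np.zeros(config.grid_shape, dtype=bool)
    for center in config.target_centers_mm:
        target_region |= _region_sphere(config, world, center) & masks.gm
    for name, region, centers in (
        ("seed", seed_region, [config.seed_center_mm]),
        ("target", target_region, list(config.target_centers_mm)),
    ):
        if not region.any():
            raise ValueError(f"{name} region at {centers} falls outside the gray matter mask")

    n = config.n_subjects
    t = config.n_timepoints
    beta = rng.normal(config.coupling_mean, config.coupling_sd, n)
    age = _truncated_normal(rng, 43.0, 12.24, 18.0, 61.0, n)
    sex = (rng.random(n) < 16.0 / 22.0).astype(int)

    runs: list[BoldRun] = []
    motions: list[MotionTrace] = []
    spike_sets: list[np.ndarray] = []
    latents: list[np.ndarray] = []
    ramp = np.arange(t) / max(t - 1, 1) - 0.5
    background = masks.gm & ~seed_region & ~target_region

    for s in range(n):
        candidates = np.flatnonzero(rng.random(t) < config.spike_rate)
        spikes = candidates[candidates > 0]
        spike_sets.append(spikes)
        motions.append(_motion_trace(rng, config, spikes))

        latent = _band_limited_signal(rng, config)
        latents.append(latent)
        wm_sig = _band_limited_signal(rng, config)
        csf_sig = _band_limited_signal(rng, config)

        data = np.full((*config.grid_shape, t), config.baseline_intensity)
        data[masks.brain] += rng.normal(
            0, config.voxel_noise_sd, (int(masks.brain.sum()), t))
        drift = rng.normal(0, config.drift_amplitude, int(masks.brain.sum()))
        data[masks.brain] += drift[:, None] * ramp[None, :]

        amp = config.signal_amplitude * config.voxel_noise_sd
        data[seed_region] += amp * latent
        data[target_region] += beta[s] * amp * latent
        nuis = config.nuisance_amplitude * config.voxel_noise_sd
        data[masks.wm] += nuis * wm_sig
        data[masks.csf] += nuis * csf_sig
        data[masks.gm] += config.leak_weight * nuis * (wm_sig + csf_sig)
        if spikes.size:
            base_jump = config.spike_amplitude_sd_units * config.voxel_noise_sd
            brain_idx = masks.brain
            for frame in spikes:
                # per-spike amplitude wobble keeps the two outlier
                # diagnostics from ranking spike frames identically
                jump = base_jump * rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0])
                data[..., frame][brain_idx] += jump
        runs.append(BoldRun(data=data, tr_seconds=config.tr_seconds,
                            affine=config.affine, subject_id=f"sub-{s + 1:02d}"))

    # outcome: slope * beta + covariate effects (centered covariates) + noise
    from .confounds import mean_fd  # deferred: avoid import cycle at module load
    fd = np.array([mean_fd(m) for m in motions])
    covs = np.column_stack([age, sex.astype(float), fd])
    covs_c = covs - covs.mean(axis=0)
    noiseless = config.outcome_slope * beta + covs_c @ np.asarray(config.covariate_effects)
    pct = noiseless + rng.normal(0, config.outcome_noise_sd, n)

    hdrs_baseline = np.round(
        _truncated_normal(rng, 22.0, 6.0, 8.0, HDRS_MAX, n)).astype(int)
    hdrs_post = np.round(hdrs_baseline * (1.0 - pct)).astype(int)
    hdrs_post = np.clip(hdrs_post, 0, HDRS_MAX)

    subjects = pd.DataFrame({
        "subject_id": [r.subject_id for r in runs],
        "age": np.round(age, 2),
        "sex": sex,
        "hdrs_baseline": hdrs_baseline,
        "hdrs_post": hdrs_post,
    })
    truth = SynthTruth(beta=beta, spike_indices=spike_sets, noiseless_outcome=noiseless,
                       seed_mask=seed_region, target_mask=target_region,
                       latent_signals=np.stack(latents))
    return runs, masks, motions, subjects, truth


def write_cohort(cohort, directory, overwrite: bool = False,
                 config: SynthConfig | None = None) -> dict:
    """Write a generated cohort to disk; returns the file manifest.

    Refuses a non-empty target directory unless ``overwrite`` is set.
    """
    runs, masks, motions, subjects, _ = cohort
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True to replace")

    manifest: dict = {"runs": [], "motion": [], "masks": {}, "n_subjects": len(runs)}
    for run, motion in zip(runs, motions):
        bold_path = directory / f"{run.subject_id}_bold.nii"
        motion_path = directory / f"{run.subject_id}_motion.txt"
        write_bold(run, bold_path)
        write_motion(motion, motion_path)
        manifest["runs"].append(bold_path.name)
        manifest["motion"].append(motion_path.name)
    for name in ("brain", "gm", "wm", "csf"):
        path = directory / f"mask_{name}.nii"
        write_mask(getattr(masks, name), masks.affine, path)
        manifest["masks"][name] = path.name
    write_subjects(subjects, directory / "subjects.tsv")
    manifest["subjects"] = "subjects.tsv"
    if config is not None:
        manifest["config"] = asdict(config)
        manifest["rng_seed"] = config.rng_seed
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
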
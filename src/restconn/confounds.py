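"""Nuisance design construction.

Framewise displacement, outlier (scrubbing) detection from within-subject
empirical percentiles of the motion / global-signal-change diagnostics,
anatomical-compartment PCA components, and the assembled confound matrix
for the two denoising strategies (``acompcor`` and ``gsr``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .volumes import BoldRun, MaskSet, MotionTrace

__all__ = [
    "ConfoundModel",
    "OutlierSeries",
    "framewise_displacement",
    "mean_fd",
    "detect_outliers",
    "scrub_regressors",
    "acompcor",
    "assemble_confounds",
]

COLUMN_SOURCES = frozenset({
    "motion", "motion_derivative", "scrub",
    "compcor_wm", "compcor_csf",
    "global_signal", "wm_mean", "csf_mean",
})


@dataclass
class ConfoundModel:
    """Per-timepoint nuisance design with labeled, provenance-tagged columns."""

    matrix: np.ndarray
    column_labels: list[str]
    column_sources: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[1] != len(self.column_labels) or \
                len(self.column_labels) != len(self.column_sources):
            raise ValueError("matrix columns, labels and sources must align")
        unknown = set(self.column_sources) - COLUMN_SOURCES
        if unknown:
            raise ValueError(f"unknown column sources: {sorted(unknown)}")
        if self.matrix.shape[1] < 1:
            raise ValueError("confound model needs at least one column")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_labels)


@dataclass
class OutlierSeries:
    """Boolean outlier flags plus the two diagnostic series behind them."""

    flags: np.ndarray
    composite_motion: np.ndarray   # FD, mm
    global_signal_change: np.ndarray  # z units
    threshold_motion: float = np.nan
    threshold_global: float = np.nan

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.composite_motion = np.asarray(self.composite_motion, dtype=np.float64)
        self.global_signal_change = np.asarray(self.global_signal_change, dtype=np.float64)
        t = self.flags.size
        if self.composite_motion.size != t or self.global_signal_change.size != t:
            raise ValueError("diagnostic series lengths must equal flag length")
        if t and self.flags.mean() > 0.5:
            raise ValueError(
                f"{int(self.flags.sum())}/{t} frames flagged (> 50%); data unusable")

    @property
    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


def framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD: sum |delta translation| + r * sum |delta rotation|; FD_1 = 0."""
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 timepoints for framewise displacement")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def mean_fd(motion: MotionTrace, head_radius_mm: float = 50.0) -> float:
    """Mean framewise displacement excluding the (zero) first frame."""
    return float(framewise_displacement(motion, head_radius_mm)[1:].mean())


def _global_signal_change(run: BoldRun, brain_mask: np.ndarray | None) -> np.ndarray:
    if brain_mask is None:
        g = run.data.reshape(-1, run.n_timepoints).mean(axis=0)
    else:
        g = run.data[brain_mask].mean(axis=0)
    dg = np.concatenate([[0.0], np.diff(g)])
    sd = dg.std()
    return dg / sd if sd > 0 else np.zeros_like(dg)


def detect_outliers(
    run: BoldRun,
    motion: MotionTrace,
    percentile: float = 97.0,
    brain_mask: np.ndarray | None = None,
    motion_threshold_mm: float | None = None,
    global_z_threshold: float | None = None,
) -> OutlierSeries:
    """Flag artifact frames from composite motion and global-signal change.

    A frame is flagged when either diagnostic STRICTLY exceeds its
    within-subject empirical ``percentile`` (so a constant series flags
    nothing).  Absolute thresholds, when given, override the percentile
    rule for the corresponding series.
    """
    if not 50.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (50, 100); got {percentile}")
    if run.n_timepoints != motion.n_timepoints:
        raise ValueError("run and motion trace have different lengths")
    fd = framewise_displacement(motion)
    gz = np.abs(_global_signal_change(run, brain_mask))

    thr_m = (np.percentile(fd, percentile) if motion_threshold_mm is None
             else float(motion_threshold_mm))
    thr_g = (np.percentile(gz, percentile) if global_z_threshold is None
             else float(global_z_threshold))
    flags = (fd > thr_m) | (gz > thr_g)
    return OutlierSeries(flags=flags, composite_motion=fd, global_signal_change=gz,
                         threshold_motion=float(thr_m), threshold_global=float(thr_g))


def scrub_regressors(outliers: OutlierSeries) -> np.ndarray:
    """One indicator column per flagged frame (t x n_flagged; may be empty)."""
    t = outliers.flags.size
    idx = outliers.flagged_indices
    cols = np.zeros((t, idx.size))
    cols[idx, np.arange(idx.size)] = 1.0
    return cols


def acompcor(run_unsmoothed: BoldRun, mask: np.ndarray, n_components: int = 5) -> np.ndarray:
    """Top principal component time series of a tissue compartment.

    Voxel series are mean-centered and linearly detrended before the
    decomposition (standard aCompCor practice).  Returned components are
    unit-variance, mutually orthogonal, ordered by explained variance.
    Must be fed the *unsmoothed* run.
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < n_components:
        raise ValueError(f"mask has {n_vox} voxels < n_components={n_components}")
    x = run_unsmoothed.data[mask]                 # (voxels, t)
    x = signal.detrend(x, axis=1, type="linear")  # removes mean + linear trend
    # right singular vectors are the component time courses
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if rank < n_components:
        raise ValueError(
            f"compartment data support only {rank} components; {n_components} requested")
    comps = vt[:n_components].T                   # (t, n_components)
    comps = comps / comps.std(axis=0, ddof=1)
    return comps


def _motion_with_derivatives(motion: MotionTrace) -> tuple[np.ndarray, np.ndarray]:
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion.params, axis=0)])
    return motion.params, deriv


def assemble_confounds(
    motion: MotionTrace,
    outliers: OutlierSeries,
    run_unsmoothed: BoldRun,
    masks: MaskSet,
    strategy: str = "acompcor",
    n_components: int = 5,
) -> ConfoundModel:
    """Full nuisance design for one run.

    ``acompcor``: 6 motion + 6 derivatives + scrub indicators + top-5 WM +
    top-5 CSF components.  ``gsr``: 6 motion + 6 derivatives + scrub
    indicators + global mean + WM mean + CSF mean.  All-zero columns
    (e.g. derivatives of a motionless trace) are dropped with a warning.
    """
    if strategy not in ("acompcor", "gsr"):
        raise ValueError(f"strategy must be 'acompcor' or 'gsr'; got {strategy!r}")
    mot, deriv = _motion_with_derivatives(motion)
    blocks = [mot, deriv]
    labels = [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    labels += [f"dmotion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    sources = ["motion"] * 6 + ["motion_derivative"] * 6

    scrub = scrub_regressors(outliers)
    if scrub.shape[1]:
        blocks.append(scrub)
        labels += [f"scrub_t{i}" for i in outliers.flagged_indices]
        sources += ["scrub"] * scrub.shape[1]

    if strategy == "acompcor":
        wm = acompcor(run_unsmoothed, masks.wm, n_components)
        csf = acompcor(run_unsmoothed, masks.csf, n_components)
        blocks += [wm, csf]
        labels += [f"compcor_wm_{i}" for i in range(wm.shape[1])]
        labels += [f"compcor_csf_{i}" for i in range(csf.shape[1])]
        sources += ["compcor_wm"] * wm.shape[1] + ["compcor_csf"] * csf.shape[1]
    else:
        means = np.column_stack([
            run_unsmoothed.data[masks.brain].mean(axis=0),
            run_unsmoothed.data[masks.wm].mean(axis=0),
            run_unsmoothed.data[masks.csf].mean(axis=0),
        ])
        blocks.append(means)
        labels += ["global_signal", "wm_mean", "csf_mean"]
        sources += ["global_signal", "wm_mean", "csf_mean"]

    matrix = np.column_stack(blocks)
    keep = np.ptp(matrix, axis=0) > 0
    if not keep.all():
        dropped = [labels[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant confound columns: {dropped}", stacklevel=2)
        matrix = matrix[:, keep]
        labels = [l for l, k in zip(labels, keep) if k]
        sources = [s for s, k in zip(sources, keep) if k]
    return ConfoundModel(matrix=matrix, column_labels=labels, column_sources=sources)
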
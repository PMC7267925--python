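"""Per-subject voxelwise connectivity: global brain connectivity (GBC)
maps and spherical-seed Fisher-z functional connectivity maps.

GBC_i = (1/n) * sum_j r_ij^2 over all in-mask voxels j, self-term
included (r_ii = 1), so values lie in (0, 1].  A signed variant (mean of
r) is available behind ``exponent="signed"`` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import BoldRun, ConnectivityMap, voxel_to_world

__all__ = ["SeedSpec", "gbc_map", "seed_timeseries", "seed_fc_map"]

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class SeedSpec:
    """Spherical seed in world mm (default: 6-mm diameter at (0, 38, 4))."""

    center_mm: tuple[float, float, float] = (0.0, 38.0, 4.0)
    diameter_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("seed diameter must be positive")


def _standardized_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that a_i . a_j = pearson r_ij; returns (rows, nonconstant)."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    out = np.zeros_like(centered)
    out[ok] = centered[ok] / norms[ok, None]
    return out, ok


def gbc_map(
    run: BoldRun,
    brain_mask: np.ndarray,
    exponent: str = "squared",
    chunk_size: int = 512,
) -> ConnectivityMap:
    """Voxelwise global connectivity over the brain mask.

    Zero-variance voxels are dropped from the mask with a warning.  The
    computation runs in voxel chunks through the t x t series Gram matrix;
    the result is independent of ``chunk_size`` (exactly, in exact
    arithmetic; asserted to 1e-10 in tests).
    """
    if exponent not in ("squared", "signed"):
        raise ValueError(f"exponent must be 'squared' or 'signed'; got {exponent!r}")
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("brain mask needs at least 2 voxels")
    x = run.data[mask]
    a, ok = _standardized_rows(x)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} zero-variance voxels from the GBC mask",
            stacklevel=2)
        idx = np.flatnonzero(mask)
        mask = mask.copy()
        mask.reshape(-1)[idx[~ok]] = False
        a = a[ok]
        if a.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant voxels in mask")
    n = a.shape[0]
    values = np.full(run.shape, np.nan)
    out = np.empty(n)
    if exponent == "squared":
        gram = a.T @ a                                # (t, t): sum_j a_j a_j^T
        for start in range(0, n, chunk_size):
            blk = a[start:start + chunk_size]
            out[start:start + chunk_size] = np.einsum("it,ts,is->i", blk, gram, blk) / n
    else:
        colsum = a.sum(axis=0)
        for start in range(0, n, chunk_size):
            out[start:start + chunk_size] = a[start:start + chunk_size] @ colsum / n
    values[mask] = out
    return ConnectivityMap(values=values, mask=mask, kind="gbc", affine=run.affine,
                           subject_id=run.subject_id or "unknown")


def sphere_voxels(affine: np.ndarray, shape, center_mm, radius_mm: float) -> np.ndarray:
    """Boolean grid of voxels whose world-mm centers lie within radius (inclusive)."""
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(np.float64)
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    d2 = np.sum((world - np.asarray(center_mm, dtype=np.float64)) ** 2, axis=-1)
    return d2 <= radius_mm**2 + 1e-9


def seed_timeseries(run: BoldRun, seed: SeedSpec, brain_mask: np.ndarray) -> np.ndarray:
    """Mean series over in-mask voxels inside the seed sphere."""
    mask = np.asarray(brain_mask, dtype=bool)
    sel = sphere_voxels(run.affine, run.shape, seed.center_mm, seed.diameter_mm / 2.0) & mask
    if not sel.any():
        # report the nearest in-mask voxel distance to aid seed placement
        idx = np.argwhere(mask)
        world = np.array([voxel_to_world(run.affine, i) for i in idx])
        nearest = float(np.sqrt(
            ((world - np.asarray(seed.center_mm)) ** 2).sum(axis=1).min()))
        raise ValueError(
            f"seed sphere at {seed.center_mm} mm (diameter {seed.diameter_mm} mm) contains "
            f"no in-mask voxel; nearest in-mask voxel center is {nearest:.2f} mm away")
    return run.data[sel].mean(axis=0)


def seed_fc_map(run: BoldRun, seed_series: np.ndarray, brain_mask: np.ndarray) -> ConnectivityMap:
    """Fisher-z map of correlations between the seed series and every voxel.

    r is clipped to +/-(1 - 1e-7) before atanh.  Constant voxel series get
    z = 0 with a warning reporting their count.  Seed-interior voxels are
    included, not masked out.
    """
    seed_series = np.asarray(seed_series, dtype=np.float64)
    if seed_series.std() == 0:
        raise ValueError("seed series is constant")
    mask = np.asarray(brain_mask, dtype=bool)
    x = run.data[mask]
    a, ok = _standardized_rows(x)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} constant voxel series set to z = 0", stacklevel=2)
    s = seed_series - seed_series.mean()
    s = s / np.linalg.norm(s)
    r = a @ s
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    z[~ok] = 0.0
    values = np.full(run.shape, np.nan)
    values[mask] = z
    return ConnectivityMap(values=values, mask=mask, kind="seed_fc_z", affine=run.affine,
                           subject_id=run.subject_id or "unknown")
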
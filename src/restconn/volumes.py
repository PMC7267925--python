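"""Shared geometric data model and NIfTI / text I/O.

Conventions: voxel indices are 0-based internally; all coordinate
*reporting* is in world mm through the image affine (RAS+). Round-trips
through disk are lossless at the declared (float32) precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldRun",
    "MaskSet",
    "MotionTrace",
    "ConnectivityMap",
    "MAP_KINDS",
    "read_bold",
    "write_bold",
    "read_masks",
    "read_mask",
    "write_mask",
    "read_motion",
    "write_motion",
    "read_subjects",
    "write_subjects",
    "world_to_voxel",
    "voxel_to_world",
    "read_map",
    "write_map",
    "write_cluster_table",
]

MAP_KINDS = frozenset({"gbc", "seed_fc_z", "t_stat", "weight"})


@dataclass
class BoldRun:
    """One subject's 4-D BOLD grid (x, y, z, t) with timing and geometry."""

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D (x, y, z, t); got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError(f"BOLD run needs t >= 2 timepoints; got t={self.data.shape[3]}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"BOLD data contains {n_bad} non-finite voxel values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        """Copy of this run carrying new voxel data, same geometry/timing."""
        return BoldRun(data=data, tr_seconds=self.tr_seconds, affine=self.affine,
                       subject_id=self.subject_id)


@dataclass
class MaskSet:
    """Brain / GM / WM / CSF boolean masks sharing one grid and affine."""

    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        for name in ("brain", "gm", "wm", "csf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        self.affine = np.asarray(self.affine, dtype=np.float64)
        shapes = {self.brain.shape, self.gm.shape, self.wm.shape, self.csf.shape}
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        if self.brain.sum() < 2:
            raise ValueError("brain mask must contain at least 2 voxels")
        if np.any(self.wm & self.csf):
            raise ValueError("WM and CSF masks overlap")
        for name in ("gm", "wm", "csf"):
            if np.any(getattr(self, name) & ~self.brain):
                raise ValueError(f"{name} mask extends outside the brain mask")


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be t x 6; got shape {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class ConnectivityMap:
    """3-D statistic map defined on a brain mask; off-mask voxels are NaN."""

    values: np.ndarray
    mask: np.ndarray
    kind: str
    affine: np.ndarray
    subject_id: str = "group"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {sorted(MAP_KINDS)}; got {self.kind!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def masked_values(self) -> np.ndarray:
        """1-D vector of on-mask values, in C order of the mask."""
        return self.values[self.mask]


def world_to_voxel(affine: np.ndarray, point_mm) -> tuple[int, int, int]:
    """Map a world-mm point to the nearest 0-based voxel index.

    Half-way ties round toward +inf on each axis.  Raises IndexError when
    the point falls outside any reasonable grid only if the caller checks;
    use :func:`world_to_voxel_checked` for bounds checking.
    """
    affine = np.asarray(affine, dtype=np.float64)
    pt = np.asarray(point_mm, dtype=np.float64)
    inv = np.linalg.inv(affine)
    vox = inv[:3, :3] @ pt + inv[:3, 3]
    # floor(x + 0.5) rounds .5 toward +inf, unlike np.round (banker's)
    idx = np.floor(vox + 0.5).astype(int)
    return tuple(int(i) for i in idx)


def world_to_voxel_checked(affine: np.ndarray, point_mm, shape) -> tuple[int, int, int]:
    idx = world_to_voxel(affine, point_mm)
    for ax, (i, n) in enumerate(zip(idx, shape)):
        if i < 0 or i >= n:
            raise IndexError(
                f"point {tuple(point_mm)} mm maps to voxel {idx}, outside the grid "
                f"on axis {ax} (size {n})"
            )
    return idx


def voxel_to_world(affine: np.ndarray, index) -> np.ndarray:
    affine = np.asarray(affine, dtype=np.float64)
    idx = np.asarray(index, dtype=np.float64)
    return affine[:3, :3] @ idx + affine[:3, 3]


def read_bold(path, tr_seconds: float, subject_id: str = "") -> BoldRun:
    """Load a 4-D NIfTI BOLD run.

    TR is taken from the caller, not the header; a header TR that disagrees
    by more than 1 ms triggers a warning only (headers are unreliable).
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D BOLD image, got {img.ndim}-D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel values")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if header_tr > 0 and abs(header_tr - tr_seconds) > 1e-3:
        warnings.warn(
            f"{path}: header TR {header_tr:.3f}s differs from configured {tr_seconds:.3f}s; "
            "using the configured value", stacklevel=2)
    return BoldRun(data=data, tr_seconds=tr_seconds, affine=np.asarray(img.affine),
                   subject_id=subject_id)


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_seconds))
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def _read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, np.asarray(img.affine)


def read_mask(path) -> np.ndarray:
    """Load a single boolean mask volume."""
    return _read_mask(path)[0]


def read_masks(brain_path, gm_path, wm_path, csf_path) -> MaskSet:
    brain, affine = _read_mask(brain_path)
    gm, _ = _read_mask(gm_path)
    wm, _ = _read_mask(wm_path)
    csf, _ = _read_mask(csf_path)
    return MaskSet(brain=brain, gm=gm, wm=wm, csf=csf, affine=affine)


def read_motion(path, subject_id: str = "") -> MotionTrace:
    params = np.loadtxt(str(path), ndmin=2)
    return MotionTrace(params=params, subject_id=subject_id)


def write_motion(trace: MotionTrace, path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.10g")


SUBJECT_COLUMNS = ["subject_id", "age", "sex", "hdrs_baseline", "hdrs_post"]


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: subjects table missing columns {missing}")
    return df


def write_subjects(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def _mask_path(path) -> Path:
    p = Path(str(path))
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + "_mask" + suffix)
    return p.with_name(name + "_mask.nii")


def write_map(cmap: ConnectivityMap, path) -> None:
    """Write a statistic map: off-mask voxels as 0, mask alongside, kind in descrip."""
    data = np.where(cmap.mask, cmap.values, 0.0).astype(np.float32)
    img = nib.Nifti1Image(data, cmap.affine)
    img.header["descrip"] = f"kind={cmap.kind};subject={cmap.subject_id}".encode()[:79]
    nib.save(img, str(path))
    write_mask(cmap.mask, cmap.affine, _mask_path(path))


def read_map(path, kind: str | None = None, subject_id: str = "group") -> ConnectivityMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    parsed = dict(item.split("=", 1) for item in descrip.split(";") if "=" in item)
    kind = kind or parsed.get("kind")
    subject_id = parsed.get("subject", subject_id)
    mask_path = _mask_path(path)
    if mask_path.exists():
        mask, _ = _read_mask(mask_path)
    else:
        mask = np.isfinite(data)
    values = np.where(mask, data, np.nan)
    return ConnectivityMap(values=values, mask=mask, kind=kind, affine=np.asarray(img.affine),
                           subject_id=subject_id)


def write_cluster_table(table: pd.DataFrame, path) -> None:
    table.to_csv(str(path), sep="\t", index=False)


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    with open(str(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
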
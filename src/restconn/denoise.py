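"""Temporal denoising chain: confound regression -> linear detrend ->
tanh despike -> ideal band-pass; plus spatial Gaussian smoothing.

The band-pass is an ideal (boxcar) frequency-domain filter with inclusive
band endpoints, so attenuation on on-grid sinusoids is exactly testable.
DC is always removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .confounds import ConfoundModel
from .volumes import BoldRun

__all__ = [
    "DenoiseParams",
    "regress_confounds",
    "detrend_linear",
    "despike_tanh",
    "bandpass",
    "smooth_gaussian",
    "run_denoise_chain",
]


@dataclass
class DenoiseParams:
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    despike_k: float = 3.0
    smoothing_fwhm_mm: float = 6.0

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not 0.0 < self.band_low_hz < self.band_high_hz:
            raise ValueError(
                f"need 0 < band_low ({self.band_low_hz}) < band_high ({self.band_high_hz})")
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high {self.band_high_hz} Hz >= Nyquist {nyquist:.4g} Hz at TR="
                f"{tr_seconds}s")
        if self.despike_k <= 0:
            raise ValueError("despike_k must be positive")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")


def _select_columns_full_rank(design: np.ndarray, labels: list[str]) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (greedy, in order)."""
    keep: list[int] = []
    rank = 0
    for j in range(design.shape[1]):
        candidate = design[:, keep + [j]]
        r = np.linalg.matrix_rank(candidate)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(f"dropping linearly dependent confound column {labels[j]!r}",
                          stacklevel=3)
    return np.asarray(keep, dtype=int)


def regress_confounds(run: BoldRun, model: ConfoundModel) -> BoldRun:
    """Per-voxel OLS residuals against the confound design (+ intercept)."""
    if model.matrix.shape[0] != run.n_timepoints:
        raise ValueError(
            f"design rows ({model.matrix.shape[0]}) != run timepoints ({run.n_timepoints})")
    design = np.column_stack([np.ones(run.n_timepoints), model.matrix])
    labels = ["intercept"] + list(model.column_labels)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        design = design[:, _select_columns_full_rank(design, labels)]
    y = run.data.reshape(-1, run.n_timepoints).T            # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return run.with_data(resid.T.reshape(run.data.shape))


def detrend_linear(run: BoldRun) -> BoldRun:
    if run.n_timepoints < 3:
        raise ValueError("need t >= 3 to detrend")
    out = signal.detrend(run.data, axis=3, type="linear")
    return run.with_data(out)


def despike_tanh(run: BoldRun, k: float = 3.0) -> BoldRun:
    """Squash per-voxel excursions through a tanh centered at the median.

    Scale a = k * 1.4826 * MAD; y = c + a*tanh((x-c)/a).  MAD = 0 leaves
    the series untouched.  Strictly monotone, so sample ordering survives.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = run.data
    c = np.median(x, axis=3, keepdims=True)
    mad = np.median(np.abs(x - c), axis=3, keepdims=True)
    a = k * 1.4826 * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        y = c + a * np.tanh((x - c) / np.where(a > 0, a, 1.0))
    out = np.where(a > 0, y, x)
    return run.with_data(out)


def bandpass(run: BoldRun, params: DenoiseParams, tr_seconds: float | None = None) -> BoldRun:
    """Ideal frequency-domain band-pass, endpoints inclusive, DC removed."""
    tr = run.tr_seconds if tr_seconds is None else tr_seconds
    params.validate(tr)
    t = run.n_timepoints
    freqs = np.fft.rfftfreq(t, d=tr)
    tol = 1e-9
    keep = (freqs >= params.band_low_hz - tol) & (freqs <= params.band_high_hz + tol)
    keep &= freqs > 0
    if not keep.any():
        raise ValueError(
            f"no frequency bins inside [{params.band_low_hz}, {params.band_high_hz}] Hz "
            f"for t={t}, TR={tr}s")
    spec = np.fft.rfft(run.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=3)
    return run.with_data(out)


def smooth_gaussian(run: BoldRun, fwhm_mm: float, voxel_size_mm: float) -> BoldRun:
    """Separable spatial Gaussian per volume, renormalized at the grid edge.

    sigma = fwhm / (2*sqrt(2*ln 2)) converted to voxel units.  Edge
    handling divides by the smoothed all-ones volume, so a constant input
    stays constant.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return run.with_data(run.data.copy())
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    norm = ndimage.gaussian_filter(np.ones(run.shape), sigma_vox, mode="constant", cval=0.0)
    out = np.empty_like(run.data)
    for ti in range(run.n_timepoints):
        sm = ndimage.gaussian_filter(run.data[..., ti], sigma_vox, mode="constant", cval=0.0)
        out[..., ti] = sm / norm
    return run.with_data(out)


def run_denoise_chain(run: BoldRun, model: ConfoundModel, params: DenoiseParams):
    """regress -> detrend -> despike -> bandpass, returning (run, stage log).

    Spatial smoothing is NOT part of this chain: it is applied to the BOLD
    input before connectivity, never before compartment-PCA extraction.
    """
    params.validate(run.tr_seconds)
    log: list[dict] = []
    out = regress_confounds(run, model)
    log.append({"stage": "regress_confounds", "n_columns": model.n_columns})
    out = detrend_linear(out)
    log.append({"stage": "detrend_linear"})
    out = despike_tanh(out, params.despike_k)
    log.append({"stage": "despike_tanh", "k": params.despike_k})
    out = bandpass(out, params)
    log.append({"stage": "bandpass",
                "band_hz": [params.band_low_hz, params.band_high_hz]})
    return out, log
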
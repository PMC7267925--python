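"""Elastic-net prediction of clinical outcome from voxelwise maps.

Leave-one-out cross-validation with strictly training-fold covariate
residualization, feature standardization and nested hyperparameter
selection (no leakage from the held-out subject), permutation
significance for r and MSE, and sign-separated weight-map cluster
reporting.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import LeaveOneOut

from .group_stats import label_clusters
from .volumes import ConnectivityMap, voxel_to_world

__all__ = [
    "PredictionSpec",
    "PredictionResult",
    "loocv_predict",
    "permutation_test",
    "weight_clusters",
    "baseline_control",
]


@dataclass
class PredictionSpec:
    feature_kind: str = "gbc"
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_alphas: int = 20
    n_perm: int = 1000
    min_cluster_voxels: int = 100
    rng_seed: int = 0
    covariate_mode: str = "residualize"     # or "append" (Frisch-Waugh)
    perm_reuse_hyperparams: bool = False
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gbc", "seed_fc_z"):
            raise ValueError("feature_kind must be 'gbc' or 'seed_fc_z'")
        if not self.l1_ratios or self.n_alphas < 1:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.covariate_mode not in ("residualize", "append"):
            raise ValueError("covariate_mode must be 'residualize' or 'append'")


@dataclass
class PredictionResult:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    mse: float
    p_r: float | None
    p_mse: float | None
    weight_map: ConnectivityMap | None
    cluster_table: pd.DataFrame | None
    fold_hyperparams: list[tuple[float, float]]
    modal_hyperparams: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "mse": self.mse,
            "p_r": self.p_r,
            "p_mse": self.p_mse,
            "predicted": [float(v) for v in self.predicted],
            "observed": [float(v) for v in self.observed],
            "fold_hyperparams": [[float(a), float(l)] for a, l in self.fold_hyperparams],
            "modal_hyperparams": [float(self.modal_hyperparams[0]),
                                  float(self.modal_hyperparams[1])],
        }


def _feature_matrix(maps: list[ConnectivityMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all maps must share one mask")
    x = np.stack([m.masked_values for m in maps])
    keep = x.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} zero-variance voxels from features",
                      stacklevel=3)
    return x[:, keep], mask, keep


def _covariate_design(covariates: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


def _fit_covariates(c_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    d = _covariate_design(c_train)
    beta, *_ = np.linalg.lstsq(d, y_train, rcond=None)
    return beta


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd_safe, (test - mu) / sd_safe, sd_safe


def _residualize_features(c_train, x_train, c_test, x_test):
    d = _covariate_design(c_train)
    beta, *_ = np.linalg.lstsq(d, x_train, rcond=None)
    return x_train - d @ beta, x_test - _covariate_design(c_test) @ beta


def _select_hyperparams(x: np.ndarray, y: np.ndarray, spec: PredictionSpec):
    """Inner-LOOCV (MSE) choice of (alpha, l1_ratio) on the training fold."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv = ElasticNetCV(l1_ratio=list(spec.l1_ratios), alphas=spec.n_alphas,
                          cv=LeaveOneOut(), max_iter=spec.max_iter)
        cv.fit(x, y)
    return float(cv.alpha_), float(cv.l1_ratio_)


def _fit_elastic_net(x: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float,
                     max_iter: int) -> ElasticNet:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=max_iter)
        model.fit(x, y)
    return model


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _modal_pair(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    counts = Counter(pairs)
    top = max(counts.values())
    # tie-break: strongest regularization first, then smaller l1_ratio
    candidates = sorted([p for p, c in counts.items() if c == top],
                        key=lambda p: (-p[0], p[1]))
    return candidates[0]


def _loocv_core(
    x: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    spec: PredictionSpec,
    fixed_hyperparams: tuple[float, float] | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Outer LOOCV loop; everything fitted on training folds only."""
    n = len(y)
    preds = np.empty(n)
    chosen: list[tuple[float, float]] = []
    for i in range(n):
        tr = np.arange(n) != i
        c_tr, c_te = c[tr], c[~tr]
        y_tr = y[tr]
        x_tr, x_te = x[tr], x[~tr]

        cov_beta = _fit_covariates(c_tr, y_tr)
        y_res_tr = y_tr - _covariate_design(c_tr) @ cov_beta
        y_cov_te = float((_covariate_design(c_te) @ cov_beta)[0])

        if spec.covariate_mode == "append":
            x_tr, x_te = _residualize_features(c_tr, x_tr, c_te, x_te)
        xs_tr, xs_te, _ = _standardize(x_tr, x_te)

        if fixed_hyperparams is None:
            alpha, l1 = _select_hyperparams(xs_tr, y_res_tr, spec)
        else:
            alpha, l1 = fixed_hyperparams
        chosen.append((alpha, l1))
        model = _fit_elastic_net(xs_tr, y_res_tr, alpha, l1, spec.max_iter)
        preds[i] = float(model.predict(xs_te)[0]) + y_cov_te
    return preds, chosen


def _covariate_array(subjects: pd.DataFrame) -> np.ndarray:
    cols = ["age", "sex", "mean_fd"]
    missing = [c for c in cols if c not in subjects.columns]
    if missing:
        raise ValueError(f"subjects table missing covariate columns {missing}")
    return subjects[cols].to_numpy(dtype=np.float64)


def _outcome(subjects: pd.DataFrame, column: str) -> np.ndarray:
    if column not in subjects.columns:
        raise ValueError(f"subjects table missing outcome column {column!r}")
    y = subjects[column].to_numpy(dtype=np.float64)
    if np.std(y) == 0:
        raise ValueError(f"outcome {column!r} is constant")
    return y


def loocv_predict(
    maps: list[ConnectivityMap],
    subjects: pd.DataFrame,
    spec: PredictionSpec,
    outcome_column: str = "hdrs_pct_change",
    run_permutations: bool = True,
) -> PredictionResult:
    """LOOCV elastic-net prediction of an outcome from voxelwise maps.

    Per held-out subject: covariate model (age, sex, mean FD) and feature
    mean/SD come from the training fold alone; (alpha, l1_ratio) chosen by
    inner LOOCV MSE; the held-out prediction is the elastic-net estimate of
    the residualized outcome plus the subject's covariate component.  The
    final weight map refits on all subjects at the modal selected
    hyperparameters and is reported on the unstandardized feature scale.
    """
    if len(maps) < 6:
        raise ValueError("need at least 6 subjects")
    if len(maps) != len(subjects):
        raise ValueError("maps and subjects table length mismatch")
    y = _outcome(subjects, outcome_column)
    c = _covariate_array(subjects)
    x, mask, keep = _feature_matrix(maps)

    preds, chosen = _loocv_core(x, y, c, spec)
    r = _pearson(preds, y)
    mse = float(np.mean((preds - y) ** 2))
    modal = _modal_pair(chosen)

    # full-sample weight map at the modal hyperparameters
    cov_beta = _fit_covariates(c, y)
    y_res = y - _covariate_design(c) @ cov_beta
    x_full = x
    if spec.covariate_mode == "append":
        x_full, _ = _residualize_features(c, x, c, x)
    xs, _, sd = _standardize(x_full, x_full)
    model = _fit_elastic_net(xs, y_res, modal[0], modal[1], spec.max_iter)
    weights_flat = model.coef_ / sd
    w_vals = np.full(mask.shape, np.nan)
    on_mask = np.zeros(int(mask.sum()))
    on_mask[keep] = weights_flat
    w_vals[mask] = on_mask
    weight_map = ConnectivityMap(values=w_vals, mask=mask, kind="weight",
                                 affine=maps[0].affine, subject_id="group")

    result = PredictionResult(
        predicted=preds, observed=y, r=r, mse=mse, p_r=None, p_mse=None,
        weight_map=weight_map, cluster_table=None, fold_hyperparams=chosen,
        modal_hyperparams=modal)
    result.cluster_table = weight_clusters(weight_map, spec.min_cluster_voxels)[1]
    if run_permutations:
        result.p_r, result.p_mse = permutation_test(maps, subjects, spec, result,
                                                    outcome_column=outcome_column)
    return result


def perm_pvalue(observed: float, null_values: np.ndarray, alternative: str) -> float:
    """Add-one permutation p: (1 + #extreme) / (1 + n_perm); NaNs never count."""
    null_values = np.asarray(null_values, dtype=np.float64)
    if alternative == "greater":
        extreme = np.sum(null_values[np.isfinite(null_values)] >= observed)
    elif alternative == "less":
        extreme = np.sum(null_values[np.isfinite(null_values)] <= observed)
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return float((1 + extreme) / (1 + null_values.size))


def permutation_test(
    maps: list[ConnectivityMap],
    subjects: pd.DataFrame,
    spec: PredictionSpec,
    observed: PredictionResult,
    outcome_column: str = "hdrs_pct_change",
) -> tuple[float, float]:
    """Shuffle the outcome vector ``n_perm`` times and re-run the LOOCV.

    Covariates stay aligned with subjects; only the outcome is permuted.
    With ``spec.perm_reuse_hyperparams`` the observed modal hyperparameters
    are reused per shuffle instead of re-running the nested selection
    (documented speed option).  p_r counts r_perm >= r_obs, p_mse counts
    mse_perm <= mse_obs, both with the add-one formula.
    """
    y = _outcome(subjects, outcome_column)
    c = _covariate_array(subjects)
    x, _, _ = _feature_matrix(maps)
    rng = np.random.default_rng(spec.rng_seed)
    fixed = observed.modal_hyperparams if spec.perm_reuse_hyperparams else None
    r_null = np.empty(spec.n_perm)
    mse_null = np.empty(spec.n_perm)
    for b in range(spec.n_perm):
        y_perm = y[rng.permutation(len(y))]
        preds, _ = _loocv_core(x, y_perm, c, spec, fixed_hyperparams=fixed)
        r_null[b] = _pearson(preds, y_perm)
        mse_null[b] = float(np.mean((preds - y_perm) ** 2))
    return (perm_pvalue(observed.r, r_null, "greater"),
            perm_pvalue(observed.mse, mse_null, "less"))


def weight_clusters(
    weight_map: ConnectivityMap,
    min_cluster_voxels: int = 100,
    connectivity: int = 18,
) -> tuple[ConnectivityMap, pd.DataFrame]:
    """Threshold a weight map by cluster extent, sign-separated.

    Positive and negative weights are labeled independently (adjacent
    opposite-sign blobs never merge); clusters below the size threshold
    are zeroed.  Returns the thresholded map and the survivor table.
    """
    vol = np.where(weight_map.mask, weight_map.values, 0.0)
    out = np.zeros_like(vol)
    rows = []
    for sgn, name in ((1, "pos"), (-1, "neg")):
        binary = sgn * vol > 0
        labels, sizes = label_clusters(binary, connectivity)
        for ci, size in enumerate(sizes, start=1):
            if size < min_cluster_voxels:
                continue
            in_cluster = labels == ci
            out[in_cluster] = vol[in_cluster]
            abs_vals = np.where(in_cluster, np.abs(vol), -np.inf)
            peak_idx = np.unravel_index(np.argmax(abs_vals), vol.shape)
            peak_mm = voxel_to_world(weight_map.affine, peak_idx)
            rows.append({
                "n_voxels": int(size),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_value": float(vol[peak_idx]),
                "sign": name,
            })
    table = pd.DataFrame(rows, columns=["n_voxels", "peak_x_mm", "peak_y_mm",
                                        "peak_z_mm", "peak_value", "sign"])
    if len(table):
        table = table.sort_values("n_voxels", ascending=False).reset_index(drop=True)
    table.insert(0, "cluster_id", np.arange(1, len(table) + 1))
    thresholded = ConnectivityMap(
        values=np.where(weight_map.mask, out, np.nan), mask=weight_map.mask,
        kind="weight", affine=weight_map.affine, subject_id=weight_map.subject_id)
    return thresholded, table


def baseline_control(
    maps: list[ConnectivityMap],
    subjects: pd.DataFrame,
    spec: PredictionSpec,
    run_permutations: bool = True,
) -> PredictionResult:
    """Specificity check: identical procedure with the baseline score as outcome."""
    return loocv_predict(maps, subjects, spec, outcome_column="hdrs_baseline",
                         run_permutations=run_permutations)
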
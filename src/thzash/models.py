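"""Regression frameworks and the shared cross-validation engine.

Four fitters: PLSR (NIPALS PLS1, LV count by minimum RMSECV), MLR (ordinary
least squares, refused on ill-conditioned or p >= n designs), PCR (principal
components up to a cumulative-variance threshold, default 95 %), and SVR
(RBF kernel, exhaustive grid over integer power-of-two exponents
C in 2^-5..2^10, gamma in 2^-10..2^5, chosen by 10-fold RMSECV).

PLSR/MLR/PCR operate on column-centered data without unit-variance scaling
(absorption spectra share units); SVR z-scores internally from calibration
statistics.  Every fold-internal statistic is recomputed from fold-training
rows only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR as _SkSVR

from ._pls import kfold_indices, pls1_fit, rmsecv_by_lv
from .preprocess import NonFiniteError, assert_finite

__all__ = [
    "CvSpec",
    "RegressionModel",
    "ModelRefusalError",
    "fit_plsr",
    "fit_mlr",
    "fit_pcr",
    "fit_svr",
    "predict",
    "cross_validate",
    "cross_val_predictions",
]


class ModelRefusalError(RuntimeError):
    """The fitter declines the design matrix (dimensionality/conditioning/NaN)."""


@dataclass(frozen=True)
class CvSpec:
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class RegressionModel:
    method: str
    payload: dict  # method-specific fitted structure
    hyperparameters: dict
    var_indices: np.ndarray | None = None  # columns of the full matrix, if subset
    metadata: dict = field(default_factory=dict)

    def predict(self, X_new):
        return predict(self, X_new)

    def to_json_dict(self):
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {
            "method": self.method,
            "hyperparameters": {k: conv(v) for k, v in self.hyperparameters.items()},
            "payload": {k: conv(v) for k, v in self.payload.items()
                        if isinstance(v, (np.ndarray, float, int, np.floating, np.integer))},
            "var_indices": conv(self.var_indices),
        }


def _refuse_nonfinite(X, y):
    rep = assert_finite(X)
    if not rep.ok:
        raise NonFiniteError(f"feature matrix refused: {rep.summary()}")
    if not np.all(np.isfinite(y)):
        raise NonFiniteError("response vector contains non-finite values")


def fit_plsr(X, y, max_lv=10, cv: CvSpec = CvSpec(), var_indices=None, n_lv=None):
    """PLS1 with the LV count minimizing out-of-fold RMSECV (trace retained).

    Pass ``n_lv`` to fix the component count and skip the CV search.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    _refuse_nonfinite(X, y)
    if n_lv is not None:
        fit = pls1_fit(X, y, n_lv)
        return RegressionModel(
            "PLSR",
            {"fit": fit},
            {"n_lv": fit.n_components},
            var_indices,
            {"fitted": fit.predict(X), "cv": cv},
        )
    rmsecv, oof = rmsecv_by_lv(X, y, max_lv, cv.folds, cv.seed)
    n_lv = int(np.argmin(rmsecv)) + 1
    fit = pls1_fit(X, y, n_lv)
    return RegressionModel(
        "PLSR",
        {"fit": fit},
        {"n_lv": n_lv},
        var_indices,
        {
            "rmsecv_trace": rmsecv,
            "rmsecv": float(rmsecv[n_lv - 1]),
            "oof_predictions": oof[:, n_lv - 1],
            "fitted": fit.predict(X),
            "cv": cv,
        },
    )


def fit_mlr(X, y, cond_limit=1e10, var_indices=None):
    """OLS with intercept; refuses p >= n or an ill-conditioned cross-product.

    The refusal is the embodiment of restricting MLR to low-dimensional,
    well-conditioned feature sets.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    _refuse_nonfinite(X, y)
    n, p = X.shape
    if p >= n:
        raise ModelRefusalError(
            f"MLR refused: p={p} >= n={n} (curse of dimensionality)"
        )
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    cond = np.linalg.cond(Xc.T @ Xc)
    if not cond < cond_limit:
        raise ModelRefusalError(
            f"MLR refused: centered cross-product condition number {cond:.3g} "
            f"exceeds limit {cond_limit:.1g} (multicollinearity)"
        )
    coef, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
    model = RegressionModel(
        "MLR",
        {"coef": coef, "x_mean": x_mean, "y_mean": float(y.mean())},
        {"condition_number": float(cond)},
        var_indices,
    )
    model.metadata["fitted"] = predict(model, X)
    return model


def fit_pcr(X, y, variance_threshold=0.95, var_indices=None):
    """Principal-component regression: smallest k with cumulative explained
    variance >= threshold, then OLS of y on those k scores."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    _refuse_nonfinite(X, y)
    if X.shape[0] < 3:
        raise ValueError("PCR needs at least 3 samples")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    keep = var > var.max() * 1e-12 if var.max() > 0 else var > 0
    var, s, U, Vt = var[keep], s[keep], U[:, keep], Vt[keep]
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, s.size)
    scores = U[:, :k] * s[:k]
    gamma, *_ = np.linalg.lstsq(scores, y - y.mean(), rcond=None)
    coef = Vt[:k].T @ gamma
    model = RegressionModel(
        "PCR",
        {"coef": coef, "x_mean": x_mean, "y_mean": float(y.mean())},
        {"n_pc": k, "variance_threshold": variance_threshold},
        var_indices,
    )
    model.metadata["fitted"] = predict(model, X)
    return model


def fit_svr(
    X,
    y,
    C_exponents=range(-5, 11),
    gamma_exponents=range(-10, 6),
    cv: CvSpec = CvSpec(),
    var_indices=None,
):
    """RBF-kernel SVR over the integer power-of-two grid, scored by RMSECV.

    X is z-scored internally from calibration statistics; epsilon is fixed at
    0.01 * sd(y).  Ties resolve to smaller C, then smaller gamma.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    _refuse_nonfinite(X, y)
    sd_y = np.std(y, ddof=1)
    if sd_y < 1e-15:
        raise ValueError("degenerate response: zero variance")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    sigma[sigma < 1e-15] = 1.0
    Z = (X - mu) / sigma
    eps = 0.01 * sd_y
    folds = kfold_indices(len(y), cv.folds, cv.seed)
    best = None
    for ce in C_exponents:
        for ge in gamma_exponents:
            C, gamma = 2.0**ce, 2.0**ge
            oof = np.empty_like(y)
            for train, test in folds:
                m = _SkSVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
                m.fit(Z[train], y[train])
                oof[test] = m.predict(Z[test])
            rmsecv = float(np.sqrt(np.mean((oof - y) ** 2)))
            if best is None or rmsecv < best[0]:
                best = (rmsecv, C, gamma)
    rmsecv, C, gamma = best
    final = _SkSVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
    final.fit(Z, y)
    model = RegressionModel(
        "SVR",
        {"estimator": final, "x_mean": mu, "x_scale": sigma},
        {"C": C, "gamma": gamma, "epsilon": eps},
        var_indices,
        {"rmsecv": rmsecv, "cv": cv},
    )
    model.metadata["fitted"] = predict(model, X)
    return model


def _take_columns(model, X_new):
    X_new = np.asarray(X_new, float)
    if model.var_indices is None:
        return X_new
    idx = np.asarray(model.var_indices, int)
    if X_new.shape[1] > idx.max():
        return X_new[:, idx]
    if X_new.shape[1] == idx.size:
        return X_new  # already subset
    missing = idx[idx >= X_new.shape[1]].tolist()
    raise ValueError(f"prediction matrix is missing variable indices {missing}")


def predict(model, X_new):
    """Apply a fitted model's stored centering/scaling and functional form.

    Never re-estimates any statistic from ``X_new``.
    """
    X_new = _take_columns(model, X_new)
    if model.method == "PLSR":
        return model.payload["fit"].predict(X_new, model.hyperparameters["n_lv"])
    if model.method in ("MLR", "PCR"):
        p = model.payload
        return p["y_mean"] + (X_new - p["x_mean"]) @ p["coef"]
    if model.method == "SVR":
        p = model.payload
        return p["estimator"].predict((X_new - p["x_mean"]) / p["x_scale"])
    raise ValueError(f"unknown model method {model.method!r}")


def cross_val_predictions(fitter, X, y, cv: CvSpec = CvSpec()):
    """Out-of-fold predictions over all rows; the full fold pipeline
    (centering, scaling, hyperparameter choice) refits inside each fold."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    oof = np.empty_like(y)
    for train, test in kfold_indices(len(y), cv.folds, cv.seed):
        if train.size < 2:
            raise ValueError("a fold has fewer than 2 training samples")
        model = fitter(X[train], y[train])
        oof[test] = predict(model, X[test])
    return oof


def cross_validate(fitter, X, y, cv: CvSpec = CvSpec()):
    """RMSECV = sqrt(mean squared out-of-fold error) over all n rows."""
    oof = cross_val_predictions(fitter, X, y, cv)
    return float(np.sqrt(np.mean((oof - np.asarray(y, float).ravel()) ** 2)))
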
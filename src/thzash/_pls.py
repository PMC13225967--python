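"""Fast single-response PLS (NIPALS) and seeded k-fold helpers.

Internal engine shared by the model fitters and the wavelength selectors;
everything is plain numpy so a selector can afford thousands of fits.
"""
from __future__ import annotations

import numpy as np

__all__ = ["PLS1Fit", "pls1_fit", "pls1_coefficients", "kfold_indices", "rmsecv_by_lv"]


class PLS1Fit:
    """Result of a NIPALS PLS1 fit; coefficients available for 1..n_components."""

    __slots__ = ("x_mean", "y_mean", "W", "P", "q", "n_components", "B")

    def __init__(self, x_mean, y_mean, W, P, q, n_components, B):
        self.x_mean = x_mean
        self.y_mean = y_mean
        self.W = W
        self.P = P
        self.q = q
        self.n_components = n_components  # components actually extracted
        self.B = B  # (p, n_components); column a-1 = coefficients with a LVs

    def predict(self, X, n_lv=None):
        a = self.n_components if n_lv is None else min(n_lv, self.n_components)
        if a < 1:
            return np.full(len(X), self.y_mean)
        return self.y_mean + (np.asarray(X, float) - self.x_mean) @ self.B[:, a - 1]

    def predict_all(self, X):
        """Predictions for every LV count: (n, n_components) matrix."""
        if self.n_components == 0:
            return np.full((len(X), 1), self.y_mean)
        return self.y_mean + (np.asarray(X, float) - self.x_mean) @ self.B


def pls1_fit(X, y, max_lv):
    """NIPALS PLS1 on column-centered X (single response, no y-deflation)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    max_lv = int(max(1, min(max_lv, n - 1, p)))
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    W = np.empty((p, max_lv))
    P = np.empty((p, max_lv))
    q = np.empty(max_lv)
    a = 0
    while a < max_lv:
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p_load = (Xc.T @ t) / tt
        W[:, a] = w
        P[:, a] = p_load
        q[a] = (yc @ t) / tt
        Xc -= np.outer(t, p_load)
        a += 1
    W, P, q = W[:, :a], P[:, :a], q[:a]
    B = pls1_coefficients(W, P, q)
    return PLS1Fit(x_mean, y_mean, W, P, q, a, B)


def pls1_coefficients(W, P, q):
    """Coefficient matrix for every truncation 1..A of the component sequence.

    B_a = W_a (P_a' W_a)^{-1} q_a; P'W is unit upper triangular under NIPALS,
    so the leading sub-systems are solved by truncation.
    """
    A = W.shape[1]
    B = np.empty((W.shape[0], A))
    if A == 0:
        return B
    PtW = P.T @ W
    for a in range(1, A + 1):
        r = np.linalg.solve(PtW[:a, :a], q[:a])
        B[:, a - 1] = W[:, :a] @ r
    return B


def kfold_indices(n, folds, seed):
    """Deterministic shuffled fold assignment: list of (train_idx, test_idx)."""
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, n={n}], got {folds}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    splits = np.array_split(perm, folds)
    out = []
    for i, test in enumerate(splits):
        train = np.concatenate([s for j, s in enumerate(splits) if j != i])
        out.append((np.sort(train), np.sort(test)))
    return out


def rmsecv_by_lv(X, y, max_lv, folds, seed):
    """Out-of-fold RMSECV for each LV count 1..max_lv (padded where rank-limited).

    Returns (rmsecv, oof) where rmsecv has length max_lv_effective and
    oof[:, a-1] are the assembled out-of-fold predictions using a LVs.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    max_lv = int(max(1, min(max_lv, n - 2, p)))  # every fold keeps >= max_lv+1 rows
    oof = np.empty((n, max_lv))
    for train, test in kfold_indices(n, folds, seed):
        fit = pls1_fit(X[train], y[train], max_lv)
        pred = fit.predict_all(X[test])
        if pred.shape[1] < max_lv:  # rank collapse inside a fold: repeat last column
            pad = np.repeat(pred[:, -1:], max_lv - pred.shape[1], axis=1)
            pred = np.hstack([pred, pad])
        oof[test] = pred
    resid = oof - y[:, None]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    return rmsecv, oof
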
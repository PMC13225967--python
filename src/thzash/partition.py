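"""Calibration/prediction partitioning and cohort descriptive statistics.

The split follows a stratified Kennard-Stone (KS) design: the global
calibration size is the nearest integer to n*ratio/(ratio+1), allocated to
cultivar strata by largest remainder, and KS maximin selection then runs
inside each stratum on its spectra.  With 183 samples at 3:1 this yields
exactly 137 calibration and 46 prediction samples.  Tukey 1.5*IQR fences
flag (but never remove) outlying reference values, and a two-sample t-test
quantifies the calibration/prediction mean difference the KS design induces.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SplitAssignment",
    "kennard_stone",
    "stratified_split",
    "tukey_outliers",
    "two_sample_t",
]


@dataclass
class SplitAssignment:
    calibration_ids: list
    prediction_ids: list
    ratio: float
    strata: dict  # sample_id -> stratum label

    def to_json(self):
        return json.dumps(
            {"calibration": list(self.calibration_ids),
             "prediction": list(self.prediction_ids)},
            indent=2,
        )

    def apply(self, table, column="set"):
        """Write calibration/prediction labels into a sample table copy."""
        out = table.copy()
        cal = set(self.calibration_ids)
        pred = set(self.prediction_ids)
        out[column] = [
            "calibration" if s in cal else "prediction" if s in pred else "unassigned"
            for s in out.sample_id
        ]
        return out


def kennard_stone(X, k):
    """Deterministic KS maximin selection of k row indices.

    Seeds with the two mutually farthest rows (Euclidean), then repeatedly
    adds the row maximizing its minimum distance to the selected set.  Ties
    break to the lowest row index (argmax takes the first maximum).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("KS requires finite rows")
    sq = np.sum(X**2, axis=1)
    D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0))
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    for _ in range(k - 2):
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return np.array(sorted(selected))


def _nearest_int(x):
    return int(np.floor(x + 0.5))


def stratified_split(X, table, ratio=3.0, strata_column="cultivar"):
    """Stratified KS split of a cohort into calibration/prediction sets.

    ``X`` holds one spectrum per row of ``table`` (typically the preprocessed
    valid-band absorption spectra — KS distances live in spectral space).
    The global calibration count is the nearest integer to
    n*ratio/(ratio+1); per-stratum counts follow by largest remainder in
    label order, and KS runs within each stratum.
    """
    X = np.asarray(X, float)
    n = len(table)
    if X.shape[0] != n:
        raise ValueError("spectral matrix and table row counts differ")
    n_cal = _nearest_int(n * ratio / (ratio + 1.0))
    labels = table[strata_column].tolist()
    uniq = list(dict.fromkeys(labels))  # first-appearance order
    sizes = np.array([labels.count(u) for u in uniq], float)
    if np.any(sizes < 2):
        small = uniq[int(np.argmin(sizes))]
        raise ValueError(f"stratum {small!r} has fewer than 2 samples; KS undefined")
    quotas = n_cal * sizes / n
    alloc = np.floor(quotas).astype(int)
    rem = n_cal - alloc.sum()
    order = np.argsort(-(quotas - alloc), kind="stable")
    for idx in order[:rem]:
        alloc[idx] += 1
    alloc = np.minimum(np.maximum(alloc, 2), sizes.astype(int))

    ids = table.sample_id.tolist()
    cal_ids = []
    for u, k in zip(uniq, alloc):
        rows = [i for i, lab in enumerate(labels) if lab == u]
        picked = kennard_stone(X[rows], int(k))
        cal_ids.extend(ids[rows[p]] for p in picked)
    cal_set = set(cal_ids)
    pred_ids = [s for s in ids if s not in cal_set]
    cal_ids = [s for s in ids if s in cal_set]  # restore table order
    return SplitAssignment(cal_ids, pred_ids, ratio, dict(zip(ids, labels)))


def tukey_outliers(y, k=1.5):
    """Boolean flags for values outside the Tukey fences [Q1-k*IQR, Q3+k*IQR].

    Quartiles use linear interpolation.  Flagged samples are retained by the
    caller — flagging is descriptive, not a removal rule.
    """
    y = np.asarray(y, float)
    if y.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    return (y < q1 - k * iqr) | (y > q3 + k * iqr)


def two_sample_t(y1, y2, equal_var=True):
    """Two-sided independent-samples t-test; pooled variance by default."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    if y1.size < 2 or y2.size < 2:
        raise ValueError("both groups need at least 2 values")
    if np.var(y1) == 0 and np.var(y2) == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t, p = stats.ttest_ind(y1, y2, equal_var=equal_var)
    return float(t), float(p)
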
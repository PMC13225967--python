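"""Spectral preprocessing operators and non-finite diagnostics.

Five operators common in chemometrics: Savitzky-Golay smoothing (SG), first
and second SG derivatives (D1/D2), standard normal variate (SNV) and
multiplicative scatter correction (MSC).  SNV divides each spectrum by its
own standard deviation, so a (near-)constant spectrum produces non-finite
values; these are surfaced in diagnostics and by :func:`assert_finite`,
which downstream model fitting uses to refuse invalid feature matrices
rather than silently propagating NaNs.

"3-point average" smoothing is realized as SG window 3 / polyorder 1, which
on interior points is exactly the moving average; SG window 3 / polyorder 2
would be the identity and could not suppress noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessSpec",
    "FiniteReport",
    "NonFiniteError",
    "sg_smooth",
    "sg_derivative",
    "snv",
    "msc",
    "assert_finite",
    "apply_preprocess",
]


class NonFiniteError(ValueError):
    """A feature matrix contains non-finite entries; fitting is refused."""


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing choice; ``method`` in {none, SG, D1, D2, SNV, MSC}."""

    method: str = "none"
    sg_window: int = 3
    sg_polyorder: int = 1
    deriv_window: int = 5
    deriv_polyorder: int = 2

    def __post_init__(self):
        if self.method not in ("none", "SG", "D1", "D2", "SNV", "MSC"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")


@dataclass
class FiniteReport:
    """Locations of non-finite entries, plus per-row diagnostics from SNV/MSC."""

    entries: list = field(default_factory=list)  # (row, col) pairs
    flagged_rows: dict = field(default_factory=dict)  # row index -> reason

    @property
    def ok(self):
        return not self.entries and not self.flagged_rows

    def summary(self):
        if self.ok:
            return "all entries finite"
        rows = sorted({r for r, _ in self.entries} | set(self.flagged_rows))
        return f"{len(self.entries)} non-finite entries in rows {rows}"


def _check_window(window, polyorder):
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"SG window {window} must exceed polyorder {polyorder}")


def sg_smooth(X, window=3, polyorder=1):
    """Per-spectrum Savitzky-Golay smoothing; edges by truncated-window polyfit."""
    X = np.asarray(X, float)
    _check_window(window, polyorder)
    if window > X.shape[-1]:
        raise ValueError("SG window exceeds number of columns")
    return savgol_filter(X, window, polyorder, axis=-1, mode="interp")


def sg_derivative(X, order, window=5, polyorder=2, delta=1.0):
    """SG derivative of given order w.r.t. the frequency axis (units per delta)."""
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    X = np.asarray(X, float)
    _check_window(window, polyorder)
    return savgol_filter(
        X, window, polyorder, deriv=order, delta=delta, axis=-1, mode="interp"
    )


def snv(X):
    """Standard normal variate: per-spectrum (x - mean)/sd (sample sd).

    Rows with sd below 1e-12 produce non-finite output, reported in the
    returned diagnostics per row rather than raised.
    """
    X = np.asarray(X, float)
    if X.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 columns")
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    report = FiniteReport()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (X - mu) / sd
    for i in np.nonzero(sd.ravel() < 1e-12)[0]:
        report.flagged_rows[int(i)] = "near-zero spectrum standard deviation"
        out[i] = np.nan  # the division is meaningless: surface it, don't hide it
    bad = np.argwhere(~np.isfinite(out))
    report.entries = [tuple(map(int, rc)) for rc in bad]
    return out, report


def msc(X, reference):
    """Multiplicative scatter correction against a reference spectrum.

    Per spectrum, OLS fit x ~ a + b*reference, output (x - a)/b.  The
    reference is normally the mean calibration spectrum, frozen and reused
    for prediction rows.  Rows with |b| < 1e-12 are flagged.
    """
    X = np.asarray(X, float)
    r = np.asarray(reference, float).ravel()
    if r.size != X.shape[-1]:
        raise ValueError("reference length does not match spectra")
    rc = r - r.mean()
    denom = rc @ rc
    b = (X - X.mean(axis=-1, keepdims=True)) @ rc / denom
    a = X.mean(axis=-1) - b * r.mean()
    report = FiniteReport()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (X - a[:, None]) / b[:, None]
    for i in np.nonzero(np.abs(b) < 1e-12)[0]:
        report.flagged_rows[int(i)] = "near-zero multiplicative coefficient"
        out[i] = np.nan
    bad = np.argwhere(~np.isfinite(out))
    report.entries = [tuple(map(int, rc_)) for rc_ in bad]
    return out, report


def assert_finite(X):
    """Report (row, column) locations of non-finite entries in X."""
    X = np.asarray(X, float)
    bad = np.argwhere(~np.isfinite(X))
    return FiniteReport(entries=[tuple(map(int, rc)) for rc in bad])


def apply_preprocess(X, spec: PreprocessSpec, delta=1.0, msc_reference=None):
    """Apply one operator; returns (matrix, FiniteReport).

    ``delta`` is the frequency step (THz) for derivative units;
    ``msc_reference`` defaults to the row mean of X (callers supply the
    calibration mean to avoid leakage).
    """
    if spec.method == "none":
        return np.asarray(X, float), assert_finite(X)
    if spec.method == "SG":
        out = sg_smooth(X, spec.sg_window, spec.sg_polyorder)
        return out, assert_finite(out)
    if spec.method in ("D1", "D2"):
        order = 1 if spec.method == "D1" else 2
        out = sg_derivative(X, order, spec.deriv_window, spec.deriv_polyorder, delta)
        return out, assert_finite(out)
    if spec.method == "SNV":
        return snv(X)
    if spec.method == "MSC":
        ref = np.asarray(X, float).mean(axis=0) if msc_reference is None else msc_reference
        return msc(X, ref)
    raise ValueError(f"unknown preprocessing method {spec.method!r}")
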
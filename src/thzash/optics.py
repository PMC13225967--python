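"""Frequency-domain conversion and optical-parameter extraction.

Time-domain pulses are Fourier-transformed; sample and reference amplitude
and phase then give the four spectral datasets used for modeling: raw
frequency-domain magnitude, absorption coefficient alpha(nu), transmittance
T(nu) and refractive index n(nu), under the standard thin-pellet first-pass
transmission model:

    n(nu)     = 1 + c * dphi(nu) / (2 pi nu d)
    alpha(nu) = (2/d) * ln[ rho(nu) * A_ref(nu) / A_samp(nu) ]   (cm^-1)
    T(nu)     = (A_samp / A_ref)^2

with dphi the unwrapped reference-minus-sample phase (positive for an
optically denser sample under the e^{-i omega t} FFT sign convention),
rho = 4n/(n+1)^2 the optional Fresnel first-pass loss (off by default) and
d the pellet thickness.  Replicate spectra of one sample are averaged in the
complex domain before any parameter extraction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import C_MM_PER_PS

__all__ = [
    "FrequencySpectrum",
    "SpectralDataset",
    "EmptyBandError",
    "to_frequency_domain",
    "average_spectra",
    "compute_refractive_index",
    "compute_absorption",
    "compute_transmittance",
    "screen_valid_band",
    "build_datasets",
]

PARAMETERS = ("frequency_domain", "absorption", "transmittance", "refractive_index")


class EmptyBandError(RuntimeError):
    """No frequency point passed the SNR screen."""


@dataclass
class FrequencySpectrum:
    freq_THz: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray  # unwrapped from the low-frequency end, rad
    sample_id: str = ""
    replicate: int = 0

    @property
    def complex(self):
        return self.magnitude * np.exp(1j * self.phase)


@dataclass
class SpectralDataset:
    """Samples x frequency matrix of one optical parameter plus valid-band mask."""

    parameter: str
    freq_THz: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray
    sample_ids: list

    def valid(self):
        """(frequencies, matrix) restricted to the valid band."""
        return self.freq_THz[self.valid_mask], self.values[:, self.valid_mask]

    def to_frame(self, masked=True):
        f, v = (self.freq_THz, self.values) if not masked else self.valid()
        cols = [f"{x:.6f}" for x in f]
        df = pd.DataFrame(v, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path, masked=True):
        self.to_frame(masked).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, parameter="absorption"):
        df = pd.read_csv(path)
        ids = df["sample_id"].astype(str).tolist()
        freq = np.array([float(c) for c in df.columns[1:]])
        vals = df.iloc[:, 1:].to_numpy(float)
        return cls(parameter, freq, vals, np.ones(freq.size, bool), ids)


def to_frequency_domain(trace, window="none", zero_pad_factor=1):
    """Discrete Fourier transform of one trace -> :class:`FrequencySpectrum`.

    The time axis must be uniform; the first non-uniform step is named in the
    error.  Phase is unwrapped starting from the low-frequency end.
    """
    t = trace.time_ps
    steps = np.diff(t)
    dt = steps[0]
    bad = np.nonzero(np.abs(steps - dt) > 1e-9 * max(dt, 1.0))[0]
    if bad.size:
        raise ValueError(
            f"non-uniform time axis: step {bad[0]} has dt={steps[bad[0]]:.6g} "
            f"(expected {dt:.6g})"
        )
    amp = trace.amplitude
    if window == "hann":
        amp = amp * np.hanning(amp.size)
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    n = int(amp.size * zero_pad_factor)
    spec = np.fft.rfft(amp, n)
    freq = np.fft.rfftfreq(n, dt)
    return FrequencySpectrum(
        freq, np.abs(spec), np.unwrap(np.angle(spec)), trace.sample_id, trace.replicate
    )


def average_spectra(spectra):
    """Average replicate spectra of one sample in the complex domain."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freq_THz
    for s in spectra[1:]:
        if not np.array_equal(s.freq_THz, f0):
            raise ValueError("spectra are not on a common frequency grid")
    mean = np.mean([s.complex for s in spectra], axis=0)
    return FrequencySpectrum(
        f0, np.abs(mean), np.unwrap(np.angle(mean)), spectra[0].sample_id, -1
    )


def _phase_difference(sample, reference, anchor_points=40):
    """Unwrapped reference-minus-sample phase with the 2*pi offset removed.

    Anchored at the low-frequency end of the usable band: a line fitted
    through the lowest ``anchor_points`` frequencies where the reference
    magnitude is appreciable (> 20 % of its peak, skipping drift-dominated
    bins) is extrapolated to nu = 0 and the nearest multiple of 2*pi
    subtracted.
    """
    dphi = np.unwrap(reference.phase - sample.phase)
    f = reference.freq_THz
    strong = np.nonzero((f > 0) & (reference.magnitude > 0.2 * reference.magnitude.max()))[0]
    if strong.size < 2:
        strong = np.nonzero(f > 0)[0]
    k = strong[: max(2, min(anchor_points, strong.size))]
    # re-unwrap from the anchor outward so drift glitches below the band
    # cannot shift the branch inside it
    dphi_band = np.unwrap(dphi[k[0]:])
    dphi = np.concatenate([dphi[: k[0]], dphi_band])
    slope, intercept = np.polyfit(f[k], dphi[k], 1)
    dphi = dphi - 2 * np.pi * np.round(intercept / (2 * np.pi))
    return dphi


def compute_refractive_index(sample, reference, thickness_mm):
    """n(nu) = 1 + c*dphi/(2 pi nu d); the nu=0 point is excluded."""
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if not np.array_equal(sample.freq_THz, reference.freq_THz):
        raise ValueError("sample and reference are not on a common frequency grid")
    dphi = _phase_difference(sample, reference)
    f = reference.freq_THz
    n = np.full(f.shape, np.nan)
    pos = f > 0
    n[pos] = 1.0 + C_MM_PER_PS * dphi[pos] / (2 * np.pi * f[pos] * thickness_mm)
    return n


def compute_absorption(sample, reference, thickness_mm, fresnel=False):
    """alpha(nu) in cm^-1; non-positive sample amplitudes yield NaN (masked later)."""
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if not np.array_equal(sample.freq_THz, reference.freq_THz):
        raise ValueError("sample and reference are not on a common frequency grid")
    d_cm = thickness_mm / 10.0
    a_s = sample.magnitude
    a_r = reference.magnitude
    rho = 1.0
    if fresnel:
        n = compute_refractive_index(sample, reference, thickness_mm)
        rho = 4.0 * n / (n + 1.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rho * a_r / a_s
        alpha = (2.0 / d_cm) * np.log(ratio)
    alpha[~(a_s > 0)] = np.nan
    return alpha


def compute_transmittance(sample, reference):
    """T(nu) = (A_samp/A_ref)^2; zero reference amplitude yields NaN."""
    if not np.array_equal(sample.freq_THz, reference.freq_THz):
        raise ValueError("sample and reference are not on a common frequency grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (sample.magnitude / reference.magnitude) ** 2
    T[reference.magnitude == 0] = np.nan
    return T


def screen_valid_band(reference_spectra, sample_spectra=None, snr_floor_dB=10.0):
    """Longest contiguous run where the reference clears the noise floor.

    The noise floor is the per-frequency s.d. across replicate reference
    spectra; with a single reference, replicate scatter of the sample spectra
    (s.d. across replicates, averaged over samples) serves as the estimate.
    Points with SNR >= ``snr_floor_dB`` (20*log10 of mean reference magnitude
    over the floor) are candidates; the longest contiguous run is returned as
    a boolean mask, to be applied to all datasets identically.
    """
    if isinstance(reference_spectra, FrequencySpectrum):
        refs = [reference_spectra]
    else:
        refs = list(reference_spectra)
    mean_ref = np.mean([r.magnitude for r in refs], axis=0)
    if len(refs) >= 2:
        floor = np.std([r.magnitude for r in refs], axis=0, ddof=1)
    elif sample_spectra:
        by_sample = {}
        for s in sample_spectra:
            by_sample.setdefault(s.sample_id, []).append(s.magnitude)
        sds = [
            np.std(np.asarray(mags), axis=0, ddof=1)
            for mags in by_sample.values()
            if len(mags) >= 2
        ]
        if not sds:
            raise ValueError(
                "need >=2 reference replicates or sample replicates for a noise floor"
            )
        floor = np.mean(sds, axis=0)
    else:
        raise ValueError("need replicate spectra to estimate the noise floor")
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_db = 20.0 * np.log10(np.where(floor > 0, mean_ref / np.maximum(floor, 1e-300), np.inf))
    ok = snr_db >= snr_floor_dB
    if not ok.any():
        raise EmptyBandError(
            f"no frequency point reaches {snr_floor_dB} dB above the noise floor"
        )
    # longest contiguous run of True
    best_len, best_start, run_start = 0, 0, None
    for i, v in enumerate(np.append(ok, False)):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    mask = np.zeros(ok.size, bool)
    mask[best_start : best_start + best_len] = True
    return mask


def build_datasets(
    traces,
    reference,
    table,
    freq_range=(0.1, 4.5),
    snr_floor_dB=10.0,
    window="none",
    fresnel=False,
):
    """Full extraction: traces -> the four screened :class:`SpectralDataset` s.

    Replicates are averaged in the complex domain per sample; the SNR screen
    is computed once (on the instrument band) and applied to every dataset.
    Returns a dict keyed by parameter name.
    """
    ref_spec = to_frequency_domain(reference, window)
    by_sample = {}
    all_specs = []
    for tr in traces:
        if tr.sample_id == "REF":
            continue
        s = to_frequency_domain(tr, window)
        by_sample.setdefault(tr.sample_id, []).append(s)
        all_specs.append(s)

    thickness = dict(zip(table.sample_id, table.thickness_mm))
    sample_ids = [sid for sid in table.sample_id if sid in by_sample]

    lo, hi = freq_range
    band = (ref_spec.freq_THz >= lo - 1e-9) & (ref_spec.freq_THz <= hi + 1e-9)

    def cut(x):
        return x[band]

    freq = cut(ref_spec.freq_THz)
    mats = {p: [] for p in PARAMETERS}
    for sid in sample_ids:
        avg = average_spectra(by_sample[sid])
        d = thickness[sid]
        mats["frequency_domain"].append(cut(avg.magnitude))
        mats["absorption"].append(cut(compute_absorption(avg, ref_spec, d, fresnel)))
        mats["transmittance"].append(cut(compute_transmittance(avg, ref_spec)))
        mats["refractive_index"].append(
            cut(compute_refractive_index(avg, ref_spec, d))
        )

    band_specs = [
        FrequencySpectrum(freq, cut(s.magnitude), cut(s.phase), s.sample_id, s.replicate)
        for s in all_specs
    ]
    ref_band = FrequencySpectrum(freq, cut(ref_spec.magnitude), cut(ref_spec.phase))
    mask = screen_valid_band(ref_band, band_specs, snr_floor_dB)

    return {
        p: SpectralDataset(p, freq, np.asarray(mats[p]), mask, list(sample_ids))
        for p in PARAMETERS
    }
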
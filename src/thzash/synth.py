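"""Synthetic THz-TDS cohorts with a known ash → absorption forward model.

The study system is transmission THz time-domain spectroscopy of pressed
wheat-flour/PE pellets: a single-cycle THz pulse passes through a pellet of
thickness ``d`` and is delayed by ``(n_eff - 1) d / c`` and attenuated in the
frequency domain by ``exp(-alpha(nu) d / 2)`` (field amplitude).  The
generator links the absorption coefficient to a known ash mass fraction
through Gaussian mineral resonance bands,

    alpha(nu; ash) = baseline + sum_b (s0_b + slope_b * ash) * G(nu; c_b, w_b),

so every downstream stage (optical-constant extraction, preprocessing,
variable selection, regression) can be exercised against ground truth.
Defaults emulate the wheat-flour cohort: 183 samples over three cultivars,
ash 0.36-0.71 %, pellet thickness 1.2 +/- 0.5 mm, 0.1-4.5 THz spectra,
three replicate traces per sample.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MineralBand",
    "CohortConfig",
    "TimeDomainTrace",
    "InvalidConfigError",
    "reference_pulse",
    "alpha_model",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "planted_cohort",
]

C_MM_PER_PS = 0.299792458  # vacuum speed of light, mm/ps (1 THz = 1/ps)


class InvalidConfigError(ValueError):
    """Raised for generator configurations that violate an invariant."""


@dataclass(frozen=True)
class MineralBand:
    """One Gaussian absorption band.

    ``slope`` is the ash sensitivity in cm^-1 per % ash at band center;
    ``strength0`` is an ash-independent pedestal (a decoy band has
    slope 0 and strength0 > 0).
    """

    center_THz: float
    width_THz: float
    slope: float
    strength0: float = 0.0


def _default_bands():
    # Four ash-sensitive mineral bands in the 0.1-1.1 THz region (collective
    # vibration / phonon resonance range of inorganic crystals) plus one
    # ash-insensitive decoy at 2.0 THz.
    return (
        MineralBand(0.30, 0.06, 30.0),
        MineralBand(0.55, 0.06, 24.0),
        MineralBand(0.80, 0.07, 28.0),
        MineralBand(1.05, 0.07, 22.0),
        MineralBand(2.00, 0.10, 0.0, strength0=8.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort; defaults are the study conditions."""

    n_samples: int = 183
    cultivars: tuple = (
        ("Nongmai126", 1 / 3),
        ("Zhongyou206", 1 / 3),
        ("Changhan58", 1 / 3),
    )
    ash_range: tuple = (0.36, 0.71)
    thickness_mean_mm: float = 1.2
    thickness_jitter_mm: float = 0.5
    freq_min_THz: float = 0.1
    freq_max_THz: float = 4.5
    freq_step_THz: float = 0.0125
    mineral_bands: tuple = field(default_factory=_default_bands)
    baseline_absorption: float = 4.0  # cm^-1
    # per-sample scattering ramp s_i * nu (particle-size/packing variation):
    # s_i ~ N(mean, sd) clipped at 0, in cm^-1 per THz
    scatter_slope_mean: float = 2.0
    scatter_slope_sd: float = 1.0
    # caliper error: the recorded pellet thickness differs from the true one
    thickness_error_sd_mm: float = 0.02
    noise_sd: float = 7e-4  # a.u., additive white noise per time sample
    # low-frequency noise pedestal (delay-line drift): spectral noise rises
    # steeply below ~0.15 THz, as in real THz-TDS; scales with noise_sd
    lf_noise_boost: float = 45.0
    lf_noise_scale_THz: float = 0.02
    lf_noise_anchor_THz: float = 0.1
    replicates: int = 3
    n_eff: float = 1.5
    pulse_center_ps: float = 10.0
    pulse_width_ps: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise InvalidConfigError("n_samples must be >= 4")
        lo, hi = self.ash_range
        if not lo < hi:
            raise InvalidConfigError("ash_range min must be < max")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if len(self.mineral_bands) == 0:
            raise InvalidConfigError("mineral_bands must be non-empty")
        fr = sum(f for _, f in self.cultivars)
        if abs(fr - 1.0) > 1e-9:
            raise InvalidConfigError("cultivar fractions must sum to 1")
        for b in self.mineral_bands:
            if not (self.freq_min_THz <= b.center_THz <= self.freq_max_THz):
                raise InvalidConfigError(
                    f"band center {b.center_THz} THz outside frequency grid"
                )

    @classmethod
    def noiseless(cls, **kw):
        """A deterministic cohort: no noise, scatter or thickness error."""
        kw.setdefault("noise_sd", 0.0)
        kw.setdefault("scatter_slope_mean", 0.0)
        kw.setdefault("scatter_slope_sd", 0.0)
        kw.setdefault("thickness_error_sd_mm", 0.0)
        return cls(**kw)

    @property
    def freq_grid(self):
        n = int(round((self.freq_max_THz - self.freq_min_THz) / self.freq_step_THz)) + 1
        return self.freq_min_THz + self.freq_step_THz * np.arange(n)

    def to_json(self):
        d = dataclasses.asdict(self)
        d["mineral_bands"] = [dataclasses.asdict(b) for b in self.mineral_bands]
        d["cultivars"] = [list(c) for c in self.cultivars]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        d["mineral_bands"] = tuple(MineralBand(**b) for b in d["mineral_bands"])
        d["cultivars"] = tuple((n, f) for n, f in d["cultivars"])
        d["ash_range"] = tuple(d["ash_range"])
        return cls(**d)


@dataclass
class TimeDomainTrace:
    """One recorded THz pulse; ``sample_id == "REF"`` marks the reference."""

    sample_id: str
    replicate: int
    time_ps: np.ndarray
    amplitude: np.ndarray
    thickness_mm: float | None = None

    def __post_init__(self):
        self.time_ps = np.asarray(self.time_ps, float)
        self.amplitude = np.asarray(self.amplitude, float)
        dt = np.diff(self.time_ps)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")


def _time_grid(freq_grid):
    """Uniform time axis whose rfft grid contains ``freq_grid`` exactly."""
    freq_grid = np.asarray(freq_grid, float)
    if freq_grid.size < 16:
        raise InvalidConfigError("frequency grid needs at least 16 points")
    df = float(freq_grid[1] - freq_grid[0])
    if df <= 0 or not np.allclose(np.diff(freq_grid), df, rtol=1e-9, atol=1e-12):
        raise InvalidConfigError("frequency grid must be uniform and increasing")
    f_nyq = max(8.0, 1.5 * freq_grid[-1])  # headroom above the instrument band
    n_t = int(round(2 * f_nyq / df))
    if n_t % 2:
        n_t += 1
    dt = 1.0 / (n_t * df)
    return dt * np.arange(n_t)


def reference_pulse(freq_grid, seed=0, noise_sd=0.0, center_ps=10.0, width_ps=0.2):
    """Single-cycle reference pulse (first-derivative Gaussian, zero DC).

    The magnitude spectrum peaks near ``1/(2*pi*width_ps)`` THz and decays
    toward both grid edges, so valid-band screening is non-trivial.  ``seed``
    only matters when ``noise_sd > 0``.
    """
    t = _time_grid(freq_grid)
    u = (t - center_ps) / width_ps
    amp = -u * np.exp(-0.5 * u**2)
    if noise_sd > 0:
        amp = amp + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return TimeDomainTrace("REF", 0, t, amp, None)


def alpha_model(freq_THz, ash, config):
    """Ground-truth absorption coefficient alpha(nu; ash) in cm^-1."""
    f = np.asarray(freq_THz, float)
    a = np.full(f.shape, float(config.baseline_absorption))
    for b in config.mineral_bands:
        g = np.exp(-0.5 * ((f - b.center_THz) / b.width_THz) ** 2)
        a += (b.strength0 + b.slope * ash) * g
    return a


def _allocate_counts(total, fractions):
    """Largest-remainder integer allocation of ``total`` over ``fractions``."""
    quotas = np.asarray(fractions, float) * total
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


def _replicate_noise(rng, n_t, dt, config):
    """White measurement noise plus a low-frequency drift pedestal.

    The pedestal emulates delay-line/baseline drift: per-bin spectral noise
    amplitude ``lf_noise_boost`` times the white floor at the anchor
    frequency, decaying exponentially with scale ``lf_noise_scale_THz``.
    Everything scales with ``noise_sd`` (zero noise -> zero drift).
    """
    white = rng.normal(0.0, config.noise_sd, n_t)
    if config.lf_noise_boost <= 0 or config.noise_sd == 0:
        return white
    f = np.fft.rfftfreq(n_t, dt)
    wbs = config.noise_sd * np.sqrt(n_t / 2.0)  # per-bin white-noise sd
    shifted = np.maximum(f, 0.05) - config.lf_noise_anchor_THz
    amp = wbs * config.lf_noise_boost * np.exp(-shifted / config.lf_noise_scale_THz)
    amp[0] = 0.0
    z = (rng.normal(size=f.size) + 1j * rng.normal(size=f.size)) / np.sqrt(2.0)
    drift = np.fft.irfft(amp * z, n_t)
    return white + drift


def _sample_rng(seed, index):
    # per-sample stream derived by counter: cohort content is independent of
    # the order samples are generated in
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_cohort(config: CohortConfig):
    """Generate a cohort: (sample table, traces, reference trace).

    Each sample trace is the reference pulse delayed by ``(n_eff-1) d / c``
    and attenuated by ``exp(-alpha(nu; ash) d / 2)`` in the frequency domain,
    with additive white noise per replicate.  The returned table has columns
    sample_id, cultivar, ash_true, thickness_mm, set.
    """
    freq_grid = config.freq_grid
    ref = reference_pulse(
        freq_grid, config.seed, 0.0, config.pulse_center_ps, config.pulse_width_ps
    )
    t = ref.time_ps
    dt = t[1] - t[0]
    n_t = t.size
    R = np.fft.rfft(ref.amplitude)
    f_rfft = np.fft.rfftfreq(n_t, dt)  # THz

    counts = _allocate_counts(config.n_samples, [f for _, f in config.cultivars])
    cultivar_of = []
    for (name, _), c in zip(config.cultivars, counts):
        cultivar_of.extend([name] * c)

    lo, hi = config.ash_range
    rows = []
    traces = []
    for k in range(config.n_samples):
        rng = _sample_rng(config.seed, k)
        ash = rng.uniform(lo, hi)
        d_mm = config.thickness_mean_mm + rng.uniform(
            -config.thickness_jitter_mm, config.thickness_jitter_mm
        )
        d_mm = max(d_mm, 0.1)
        d_recorded = d_mm + (
            rng.normal(0.0, config.thickness_error_sd_mm)
            if config.thickness_error_sd_mm > 0
            else 0.0
        )
        sid = f"S{k:04d}"
        rows.append((sid, cultivar_of[k], ash, d_recorded, "unassigned"))

        alpha = alpha_model(f_rfft, ash, config)  # cm^-1
        if config.scatter_slope_sd > 0 or config.scatter_slope_mean > 0:
            s_i = max(
                0.0, rng.normal(config.scatter_slope_mean, config.scatter_slope_sd)
            )
            alpha = alpha + s_i * f_rfft
        d_cm = d_mm / 10.0
        delay_ps = (config.n_eff - 1.0) * d_mm / C_MM_PER_PS
        H = np.exp(-alpha * d_cm / 2.0) * np.exp(-2j * np.pi * f_rfft * delay_ps)
        clean = np.fft.irfft(R * H, n_t)
        for r in range(config.replicates):
            noise = (
                _replicate_noise(rng, n_t, dt, config) if config.noise_sd > 0 else 0.0
            )
            traces.append(TimeDomainTrace(sid, r, t, clean + noise, d_mm))

    table = pd.DataFrame(
        rows, columns=["sample_id", "cultivar", "ash_true", "thickness_mm", "set"]
    )
    return table, traces, ref


def write_cohort(table, traces, directory, config=None, overwrite=False):
    """Write a cohort as plain CSV files plus the generating config as JSON.

    One two-column file per trace (header ``time_ps,amplitude``), one
    ``samples.csv`` metadata table and, when given, ``config.json``.
    Refuses a directory that already holds a cohort unless ``overwrite``.
    """
    os.makedirs(directory, exist_ok=True)
    meta_path = os.path.join(directory, "samples.csv")
    if os.path.exists(meta_path) and not overwrite:
        raise FileExistsError(
            f"{directory} already contains a cohort (pass overwrite=True)"
        )
    table.to_csv(meta_path, index=False, lineterminator="\n")
    for tr in traces:
        name = f"trace_{tr.sample_id}_r{tr.replicate}.csv"
        arr = np.column_stack([tr.time_ps, tr.amplitude])
        header = "time_ps,amplitude"
        np.savetxt(
            os.path.join(directory, name),
            arr,
            delimiter=",",
            header=header,
            comments="",
            fmt="%.17g",
        )
    if config is not None:
        with open(os.path.join(directory, "config.json"), "w") as fh:
            fh.write(config.to_json())


def read_cohort(directory):
    """Read back a cohort written by :func:`write_cohort`."""
    table = pd.read_csv(os.path.join(directory, "samples.csv"))
    thick = dict(zip(table.sample_id, table.thickness_mm))
    traces = []
    ref = None
    for name in sorted(os.listdir(directory)):
        if not (name.startswith("trace_") and name.endswith(".csv")):
            continue
        stem = name[len("trace_"):-len(".csv")]
        sid, rep = stem.rsplit("_r", 1)
        arr = np.loadtxt(os.path.join(directory, name), delimiter=",", skiprows=1)
        tr = TimeDomainTrace(sid, int(rep), arr[:, 0], arr[:, 1], thick.get(sid))
        if sid == "REF":
            ref = tr
        else:
            traces.append(tr)
    config = None
    cfg_path = os.path.join(directory, "config.json")
    if os.path.exists(cfg_path):
        with open(cfg_path) as fh:
            config = CohortConfig.from_json(fh.read())
    return table, traces, ref, config


def planted_cohort(
    n_samples=120,
    n_vars=200,
    seed=0,
    snr=20.0,
    band_centers=(20, 55, 90, 125, 160),
    decoy_center=185,
    band_width=3.0,
    ash_range=(0.36, 0.71),
):
    """Absorption-like spectra with planted informative bands, for selector tests.

    Returns ``(X, y, info_bands, decoy_band)`` where ``info_bands`` is a list
    of index arrays (the >= half-maximum neighborhood of each ash-sensitive
    band) and ``decoy_band`` the analogous neighborhood of an ash-insensitive
    band whose strength varies sample-to-sample but independently of ash.
    ``snr`` is the ratio of the ash-driven signal s.d. to the noise s.d. at a
    band center.  A small per-sample additive baseline jitter emulates pellet
    thickness error, and — as in measured spectra, where the dynamic range
    collapses away from the pulse peak — noise outside the informative bands
    is several times larger than at the band centers, so full-spectrum models
    genuinely pay for carrying uninformative variables.
    """
    rng = np.random.default_rng(seed)
    y = rng.uniform(*ash_range, n_samples)
    grid = np.arange(n_vars)
    X = np.full((n_samples, n_vars), 4.0)
    slope = 30.0
    in_band = np.zeros(n_vars)
    for c in band_centers:
        g = np.exp(-0.5 * ((grid - c) / band_width) ** 2)
        X += np.outer(slope * y, g)
        in_band = np.maximum(in_band, g)
    gd = np.exp(-0.5 * ((grid - decoy_center) / band_width) ** 2)
    decoy_strength = rng.normal(slope * np.mean(ash_range), slope * np.std(y), n_samples)
    X += np.outer(decoy_strength, gd)
    noise_sd = slope * np.std(y) / snr
    col_sd = noise_sd * (6.0 - 5.0 * in_band)  # 1x at band centers, 6x far out
    X += rng.normal(0.0, 1.0, X.shape) * col_sd
    # structured high-index junk: smooth per-sample artifacts whose amplitude
    # ramps up beyond the informative region (dynamic-range collapse), so
    # models carrying those variables overfit their chance correlations
    junk_start = int(0.85 * n_vars)
    ramp = np.maximum(0.0, (grid - junk_start) / (n_vars - junk_start))
    walk = np.cumsum(rng.normal(0.0, 1.0, (n_samples, n_vars)), axis=1)
    walk -= walk.mean(axis=1, keepdims=True)
    walk /= np.maximum(walk.std(axis=1, keepdims=True), 1e-12)
    X += 20.0 * noise_sd * ramp * walk
    half = int(np.ceil(band_width * np.sqrt(2 * np.log(2))))
    info = [
        np.arange(max(c - half, 0), min(c + half + 1, n_vars)) for c in band_centers
    ]
    decoy = np.arange(max(decoy_center - half, 0), min(decoy_center + half + 1, n_vars))
    return X, y, info, decoy
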
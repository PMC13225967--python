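"""Fourier conversion, optical constants and valid-band screening."""
import numpy as np
import pytest

from thzash import optics, synth
from thzash.synth import C_MM_PER_PS, TimeDomainTrace


def _trace(amp, dt=0.05, sid="X"):
    t = dt * np.arange(len(amp))
    return TimeDomainTrace(sid, 0, t, np.asarray(amp, float))


def brute_force_dft(x):
    """O(N^2) discrete Fourier sum, the independent oracle."""
    n = len(x)
    k = np.arange(n // 2 + 1)
    ang = -2j * np.pi * np.outer(k, np.arange(n)) / n
    return np.exp(ang) @ x


def test_fft_matches_brute_force_oracle(rng):
    x = rng.normal(size=128)
    spec = optics.to_frequency_domain(_trace(x))
    oracle = brute_force_dft(x)
    np.testing.assert_allclose(spec.magnitude, np.abs(oracle), atol=1e-10)


def test_cosine_peaks_at_nearest_grid_frequency():
    dt = 0.05  # ps -> 64 ps window, df = 1/64 THz
    t = dt * np.arange(1280)
    tr = TimeDomainTrace("c", 0, t, np.cos(2 * np.pi * 1.0 * t))
    spec = optics.to_frequency_domain(tr)
    peak = spec.freq_THz[np.argmax(spec.magnitude)]
    nearest = spec.freq_THz[np.argmin(np.abs(spec.freq_THz - 1.0))]
    assert peak == nearest


def test_shift_theorem():
    rng = np.random.default_rng(0)
    x = np.zeros(512)
    x[100:130] = rng.normal(size=30)
    shift = 17
    a = optics.to_frequency_domain(_trace(x))
    b = optics.to_frequency_domain(_trace(np.roll(x, shift)))
    np.testing.assert_allclose(a.magnitude, b.magnitude, atol=1e-10)
    dt = 0.05
    dphi = np.unwrap(a.phase - b.phase)
    expected = 2 * np.pi * a.freq_THz * (-shift * dt)
    # phases only defined where magnitude is appreciable
    ok = a.magnitude > a.magnitude.max() * 1e-6
    np.testing.assert_allclose(dphi[ok], -expected[ok], atol=1e-6)


def test_nonuniform_time_axis_names_offending_step():
    t = 0.05 * np.arange(64)
    t[40:] += 0.01
    tr = TimeDomainTrace("bad", 0, t, np.ones(64))
    with pytest.raises(ValueError, match="step 39"):
        optics.to_frequency_domain(tr)


def test_identical_sample_and_reference():
    x = synth.reference_pulse(synth.CohortConfig().freq_grid)
    s = optics.to_frequency_domain(x)
    n = optics.compute_refractive_index(s, s, 1.2)
    alpha = optics.compute_absorption(s, s, 1.2)
    T = optics.compute_transmittance(s, s)
    # restrict to the pulse's spectral support (magnitude underflows at the
    # far band edge, where the ratio is undefined by construction)
    band = (s.freq_THz > 0) & (s.magnitude > 1e-30)
    np.testing.assert_allclose(n[band], 1.0, atol=1e-12)
    np.testing.assert_allclose(alpha[band], 0.0, atol=1e-12)
    np.testing.assert_allclose(T[band], 1.0, atol=1e-12)


def test_thickness_scaling_relations():
    """n-1 scales inversely with d at fixed phase; alpha halves when d doubles."""
    grid = synth.CohortConfig().freq_grid
    ref = optics.to_frequency_domain(synth.reference_pulse(grid))
    delay = 2.0  # ps
    shifted = optics.FrequencySpectrum(
        ref.freq_THz, ref.magnitude * 0.5, ref.phase - 2 * np.pi * ref.freq_THz * delay
    )
    band = (ref.freq_THz > 0) & (ref.magnitude > 1e-30)
    n1 = optics.compute_refractive_index(shifted, ref, 1.2)
    n2 = optics.compute_refractive_index(shifted, ref, 0.6)
    np.testing.assert_allclose((n2 - 1)[band], 2 * (n1 - 1)[band], rtol=1e-9)
    a1 = optics.compute_absorption(shifted, ref, 1.2)
    a2 = optics.compute_absorption(shifted, ref, 2.4)
    np.testing.assert_allclose(a2[band], a1[band] / 2, rtol=1e-9)
    np.testing.assert_allclose(a1[band], (2 / 0.12) * np.log(2.0), rtol=1e-9)


def test_noiseless_round_trip(small_noiseless_datasets):
    """Extraction inverts the forward model: alpha within 1 %, n = n_eff, T consistent."""
    cfg, table, ds = small_noiseless_datasets
    f, A = ds["absorption"].valid()
    for i, ash in enumerate(table.ash_true):
        truth = synth.alpha_model(f, ash, cfg)
        np.testing.assert_allclose(A[i], truth, rtol=0.01)
    fn, N = ds["refractive_index"].valid()
    np.testing.assert_allclose(N, cfg.n_eff, atol=0.01)
    fT, T = ds["transmittance"].valid()
    d_cm = table.thickness_mm.to_numpy()[:, None] / 10.0
    np.testing.assert_allclose(-np.log(T) / d_cm, A, atol=1e-9)


def test_transmittance_quarter_for_half_amplitude():
    grid = synth.CohortConfig().freq_grid
    ref = optics.to_frequency_domain(synth.reference_pulse(grid))
    half = optics.FrequencySpectrum(ref.freq_THz, ref.magnitude * 0.5, ref.phase)
    T = optics.compute_transmittance(half, ref)
    band = ref.magnitude > 1e-30
    np.testing.assert_allclose(T[band], 0.25, atol=1e-12)


def test_alpha_invariant_to_global_rescaling(small_noiseless_cohort):
    """A common gain factor on sample and reference cancels in alpha."""
    cfg, table, traces, ref = small_noiseless_cohort
    s = optics.to_frequency_domain(traces[0])
    r = optics.to_frequency_domain(ref)
    a1 = optics.compute_absorption(s, r, 1.2)
    s2 = optics.FrequencySpectrum(s.freq_THz, 3.7 * s.magnitude, s.phase)
    r2 = optics.FrequencySpectrum(r.freq_THz, 3.7 * r.magnitude, r.phase)
    a2 = optics.compute_absorption(s2, r2, 1.2)
    band = s.freq_THz > 0
    np.testing.assert_allclose(a1[band], a2[band], rtol=1e-12)


def test_screening_monotone_and_contract(default_datasets):
    cfg, table, ds = default_datasets
    mask = ds["absorption"].valid_mask
    # both grid endpoints are excluded by construction of the band edges
    assert not mask[0] and not mask[-1]
    assert mask.sum() > 100
    # masked datasets contain no non-finite values
    for d in ds.values():
        assert np.isfinite(d.valid()[1]).all()


def test_screening_floor_monotonicity(default_cohort):
    cfg, table, traces, ref = default_cohort
    sub = [t for t in traces if t.sample_id in set(table.sample_id[:20])]
    specs = [optics.to_frequency_domain(t) for t in sub]
    r = optics.to_frequency_domain(ref)
    m10 = optics.screen_valid_band(r, specs, 10.0)
    m25 = optics.screen_valid_band(r, specs, 25.0)
    assert m25.sum() <= m10.sum()
    assert not (m25 & ~m10).any()  # raising the floor never widens the band


def test_screening_noiseless_full_support():
    grid = synth.CohortConfig().freq_grid
    r = optics.to_frequency_domain(synth.reference_pulse(grid))
    mask = optics.screen_valid_band([r, r, r], snr_floor_dB=10.0)
    assert mask.all()  # zero replicate scatter -> infinite SNR everywhere


def test_screening_empty_band_error():
    grid = synth.CohortConfig().freq_grid
    r = optics.to_frequency_domain(synth.reference_pulse(grid, 1, noise_sd=0.3))
    r2 = optics.to_frequency_domain(synth.reference_pulse(grid, 2, noise_sd=0.3))
    with pytest.raises(optics.EmptyBandError):
        optics.screen_valid_band([r, r2], snr_floor_dB=200.0)


def test_replicate_averaging_in_complex_domain():
    grid = synth.CohortConfig().freq_grid
    p = synth.reference_pulse(grid)
    s1 = optics.to_frequency_domain(p)
    flipped = TimeDomainTrace("X", 1, p.time_ps, -p.amplitude)
    s2 = optics.to_frequency_domain(flipped)
    avg = optics.average_spectra([s1, s2])
    # opposite-phase replicates cancel in the complex mean, not in magnitude
    assert avg.magnitude.max() < 1e-10 * s1.magnitude.max()


def test_spectral_dataset_csv_round_trip(tmp_path, small_noiseless_datasets):
    cfg, table, ds = small_noiseless_datasets
    path = tmp_path / "abs.csv"
    ds["absorption"].to_csv(path)
    back = optics.SpectralDataset.from_csv(path)
    f, A = ds["absorption"].valid()
    np.testing.assert_allclose(back.freq_THz, np.round(f, 6), atol=1e-9)
    np.testing.assert_allclose(back.values, A, rtol=1e-5)
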
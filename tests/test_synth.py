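"""Synthetic-cohort generator: pulse contract, forward model, round-trips."""
import numpy as np
import pandas as pd
import pytest

from thzash import synth


def test_reference_pulse_zero_mean_and_deterministic():
    grid = synth.CohortConfig().freq_grid
    p1 = synth.reference_pulse(grid, seed=1)
    p2 = synth.reference_pulse(grid, seed=1)
    # a first-derivative Gaussian has no DC component
    assert abs(np.trapezoid(p1.amplitude, p1.time_ps)) < 1e-10
    np.testing.assert_array_equal(p1.amplitude, p2.amplitude)


def test_reference_pulse_band_edge_decay():
    """Magnitude at 1 THz dominates the 4.4 THz edge by far more than 10x."""
    grid = synth.CohortConfig().freq_grid
    p = synth.reference_pulse(grid, seed=1)
    dt = p.time_ps[1] - p.time_ps[0]
    spec = np.abs(np.fft.rfft(p.amplitude))
    f = np.fft.rfftfreq(p.amplitude.size, dt)
    m1 = spec[np.argmin(np.abs(f - 1.0))]
    m44 = spec[np.argmin(np.abs(f - 4.4))]
    assert m1 / m44 > 10


def test_reference_pulse_spectral_dynamic_range():
    """>= 40 dB between the 0.2-3 THz plateau and the upper band edge."""
    grid = synth.CohortConfig().freq_grid
    p = synth.reference_pulse(grid, seed=0)
    dt = p.time_ps[1] - p.time_ps[0]
    spec = np.abs(np.fft.rfft(p.amplitude))
    f = np.fft.rfftfreq(p.amplitude.size, dt)
    band = (f >= 0.2) & (f <= 3.0)
    edge = spec[np.argmin(np.abs(f - 4.5))]
    assert 20 * np.log10(spec[band].min() / edge) >= 40


def test_reference_pulse_degenerate_grid():
    with pytest.raises(synth.InvalidConfigError):
        synth.reference_pulse(np.linspace(0.1, 4.5, 8))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_samples": 3},
        {"ash_range": (0.7, 0.4)},
        {"noise_sd": -1.0},
        {"mineral_bands": ()},
        {"cultivars": (("A", 0.5), ("B", 0.4))},
        {"mineral_bands": (synth.MineralBand(9.0, 0.1, 1.0),)},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(synth.InvalidConfigError):
        synth.CohortConfig(**kwargs)


def test_cohort_shape_and_strata():
    cfg = synth.CohortConfig(seed=7)
    table, traces, ref = synth.generate_cohort(cfg)
    assert len(table) == 183
    assert table.cultivar.nunique() == 3
    assert len(traces) == 183 * 3
    assert table.sample_id.is_unique
    assert (table.thickness_mm > 0).all()
    lo, hi = cfg.ash_range
    assert table.ash_true.between(lo, hi).all()


def test_zero_attenuation_gives_delayed_reference():
    """noise 0, ash-insensitive config with zero absorption: trace == delayed ref."""
    band = (synth.MineralBand(1.0, 0.1, 0.0, strength0=0.0),)
    cfg = synth.CohortConfig.noiseless(
        n_samples=4,
        baseline_absorption=0.0,
        mineral_bands=band,
        thickness_jitter_mm=0.0,
        n_eff=1.0,  # zero delay: the transfer function is exactly 1
        seed=3,
    )
    table, traces, ref = synth.generate_cohort(cfg)
    for tr in traces:
        np.testing.assert_allclose(tr.amplitude, ref.amplitude, atol=1e-12)
    # with a refractive sample the magnitude spectrum is still untouched
    cfg2 = synth.CohortConfig.noiseless(
        n_samples=4, baseline_absorption=0.0, mineral_bands=band, seed=3
    )
    _, traces2, ref2 = synth.generate_cohort(cfg2)
    np.testing.assert_allclose(
        np.abs(np.fft.rfft(traces2[0].amplitude)),
        np.abs(np.fft.rfft(ref2.amplitude)),
        atol=1e-9,
    )


def test_replicate_mean_error_scales_with_replicates():
    """sd of the replicate-mean deviation shrinks like 1/sqrt(replicates)."""
    sds = {}
    for reps in (3, 48):
        cfg = synth.CohortConfig(
            n_samples=4, replicates=reps, seed=5,
            scatter_slope_mean=0.0, scatter_slope_sd=0.0, thickness_error_sd_mm=0.0,
        )
        clean = synth.CohortConfig.noiseless(
            n_samples=4, replicates=1, seed=5, thickness_jitter_mm=cfg.thickness_jitter_mm
        )
        table, traces, _ = synth.generate_cohort(cfg)
        _, clean_traces, _ = synth.generate_cohort(clean)
        mean_trace = np.mean(
            [t.amplitude for t in traces if t.sample_id == "S0000"], axis=0
        )
        sds[reps] = np.std(mean_trace - clean_traces[0].amplitude)
    ratio = sds[3] / sds[48]
    assert 2.0 < ratio < 8.0  # expect sqrt(48/3) = 4


def test_higher_ash_attenuates_more_at_band_centers():
    cfg = synth.CohortConfig.noiseless(n_samples=4, seed=1, thickness_jitter_mm=0.0)
    table, traces, ref = synth.generate_cohort(cfg)
    dt = ref.time_ps[1] - ref.time_ps[0]
    f = np.fft.rfftfreq(ref.amplitude.size, dt)
    order = np.argsort(table.ash_true.to_numpy())
    lo_tr = traces[order[0] * cfg.replicates]
    hi_tr = traces[order[-1] * cfg.replicates]
    mag_lo = np.abs(np.fft.rfft(lo_tr.amplitude))
    mag_hi = np.abs(np.fft.rfft(hi_tr.amplitude))
    for b in cfg.mineral_bands:
        if b.slope == 0:
            continue
        j = np.argmin(np.abs(f - b.center_THz))
        assert mag_hi[j] < mag_lo[j]


def test_cohort_determinism():
    cfg = synth.CohortConfig(n_samples=5, seed=42)
    t1, tr1, r1 = synth.generate_cohort(cfg)
    t2, tr2, r2 = synth.generate_cohort(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    for a, b in zip(tr1, tr2):
        np.testing.assert_allclose(a.amplitude, b.amplitude, atol=1e-12)


def test_write_read_round_trip(tmp_path):
    cfg = synth.CohortConfig(n_samples=4, seed=9)
    table, traces, ref = synth.generate_cohort(cfg)
    d = tmp_path / "cohort"
    synth.write_cohort(table, traces + [ref], d, cfg)
    files = [p for p in d.iterdir() if p.name.startswith("trace_")]
    assert len(files) == 4 * cfg.replicates + 1
    t2, tr2, ref2, cfg2 = synth.read_cohort(d)
    pd.testing.assert_frame_equal(table, t2)
    assert cfg2 == cfg
    by_key = {(t.sample_id, t.replicate): t for t in tr2}
    for t in traces:
        np.testing.assert_allclose(
            by_key[(t.sample_id, t.replicate)].amplitude, t.amplitude, atol=1e-12
        )
    with pytest.raises(FileExistsError):
        synth.write_cohort(table, traces, d)
    synth.write_cohort(table, traces + [ref], d, cfg, overwrite=True)


def test_planted_cohort_structure():
    X, y, info, decoy = synth.planted_cohort(n_samples=50, n_vars=120, seed=3,
                                             band_centers=(20, 50, 80, 95, 105),
                                             decoy_center=110)
    assert X.shape == (50, 120)
    assert len(info) == 5
    # each informative neighborhood correlates with ash far above chance
    for band in info:
        c = np.corrcoef(X[:, band].mean(axis=1), y)[0, 1]
        assert c > 0.8
    assert abs(np.corrcoef(X[:, decoy].mean(axis=1), y)[0, 1]) < 0.5
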
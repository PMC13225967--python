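"""Wavelength selectors: construction contracts and planted-band recovery."""
import numpy as np
import pytest

from thzash import select, synth
from thzash._pls import kfold_indices
from thzash.select import CarsConfig, boss, cars, ga_select, spa


def _hits(chosen, bands):
    return sum(bool(np.intersect1d(chosen, b).size) for b in bands)


def test_cars_edf_endpoints():
    p, N = 200, 100
    a = (p / 2) ** (1 / (N - 1))
    k = np.log(p / 2) / (N - 1)
    assert int(np.ceil(a * np.exp(-k * 1) * p)) == p
    assert int(np.ceil(a * np.exp(-k * N) * p)) == 2
    X, y, *_ = synth.planted_cohort(n_samples=40, n_vars=60, seed=0,
                                    band_centers=(10, 20, 30, 40, 50),
                                    decoy_center=55)
    r = cars(X, y, CarsConfig(n_runs=10, cv_folds=5, seed=0))
    assert r.diagnostics["edf_a"] == pytest.approx((60 / 2) ** (1 / 9))


def test_cars_determinism_and_trace_consistency():
    X, y, *_ = synth.planted_cohort(n_samples=60, n_vars=80, seed=2,
                                    band_centers=(10, 25, 40, 55, 65),
                                    decoy_center=72)
    cfg = CarsConfig(n_runs=20, cv_folds=5, seed=4)
    r1 = cars(X, y, cfg)
    r2 = cars(X, y, cfg)
    np.testing.assert_array_equal(r1.chosen, r2.chosen)
    np.testing.assert_array_equal(r1.rmsecv_trace, r2.rmsecv_trace)
    assert r1.rmsecv_trace[r1.best_iteration] == r1.rmsecv_trace.min()
    assert r1.chosen.size == np.unique(r1.chosen).size > 0
    assert r1.n_vars_trace[-1] >= 2


def test_cars_config_validation():
    with pytest.raises(ValueError):
        CarsConfig(n_runs=1)
    with pytest.raises(ValueError):
        CarsConfig(mc_fraction=1.5)


def test_cars_recovers_planted_bands_small():
    found = 0
    for seed in range(5):
        X, y, info, _ = synth.planted_cohort(seed=seed)
        r = cars(X, y, CarsConfig(n_runs=30, cv_folds=5, seed=seed))
        found += _hits(r.chosen, info) == 5
    assert found >= 4


def test_spa_never_keeps_duplicate_columns(rng):
    X = rng.normal(size=(30, 6))
    X[:, 3] = X[:, 0]
    y = X @ rng.normal(size=6)
    r = spa(X, y, 1, 4)
    assert not ({0, 3} <= set(r.chosen))


def test_spa_orthogonal_noiseless_exact(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(40, 8)))
    S = Q.copy()
    for j in (1, 4, 6):
        S[:, j] *= 3.0  # informative columns carry the signal power
    y = 2 * S[:, 1] - 1.5 * S[:, 4] + 0.7 * S[:, 6]
    r = spa(S, y, 1, 5)
    assert list(r.chosen) == [1, 4, 6]
    assert r.rmsecv_trace.min() == pytest.approx(0.0, abs=1e-12)


def test_spa_k1_is_brute_force_univariate(rng):
    X = rng.normal(size=(30, 6))
    y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=30)
    r = spa(X, y, 1, 1)
    folds = kfold_indices(30, 10, 0)
    scores = [select._ols_oof_rmse(X[:, [j]], y, folds) for j in range(6)]
    assert list(r.chosen) == [int(np.argmin(scores))]


def test_spa_rejects_bad_k(rng):
    X = rng.normal(size=(10, 5))
    with pytest.raises(ValueError):
        spa(X, np.ones(10), 3, 2)
    with pytest.raises(ValueError):
        spa(X, np.ones(10), 1, 20)


def test_ga_static_population_with_no_variation():
    """init_prob=1 makes every chromosome identical; with mutation off the
    population is invariant, so every variable ends at frequency 1."""
    X, y, *_ = synth.planted_cohort(n_samples=30, n_vars=20, seed=0,
                                    band_centers=(3, 7, 11, 15, 18),
                                    decoy_center=10)
    r = ga_select(X, y, pop_size=6, n_generations=3, p_mutation=0.0,
                  init_prob=1.0, cv_folds=3, seed=1)
    np.testing.assert_allclose(r.diagnostics["selection_frequency"], 1.0)
    assert list(r.chosen) == list(range(20))


def test_ga_window_covering_everything_keeps_all_present():
    X, y, *_ = synth.planted_cohort(n_samples=30, n_vars=15, seed=1,
                                    band_centers=(2, 5, 8, 11, 13),
                                    decoy_center=7)
    r = ga_select(X, y, pop_size=8, n_generations=4, freq_lower=0.0,
                  freq_upper=1.0, cv_folds=3, seed=2)
    freq = r.diagnostics["selection_frequency"]
    np.testing.assert_array_equal(r.chosen, np.arange(15))
    assert (freq >= 0).all() and (freq <= 1).all()


def test_ga_pop_size_validation():
    X = np.random.default_rng(0).normal(size=(20, 5))
    with pytest.raises(ValueError):
        ga_select(X, np.ones(20), pop_size=5)


def test_ga_determinism():
    X, y, *_ = synth.planted_cohort(n_samples=40, n_vars=40, seed=3,
                                    band_centers=(5, 13, 21, 29, 35),
                                    decoy_center=38)
    kw = dict(pop_size=8, n_generations=5, cv_folds=3, seed=9)
    np.testing.assert_array_equal(ga_select(X, y, **kw).chosen,
                                  ga_select(X, y, **kw).chosen)


def test_boss_weights_and_single_iteration():
    X, y, *_ = synth.planted_cohort(n_samples=50, n_vars=60, seed=4,
                                    band_centers=(8, 20, 32, 44, 52),
                                    decoy_center=57)
    r = boss(X, y, max_lv=8, n_iterations=1, n_bootstrap_models=25,
             cv_folds=5, seed=5)
    assert r.diagnostics["final_weights"].sum() == pytest.approx(1.0)
    assert (r.diagnostics["final_weights"] >= 0).all()
    assert r.best_iteration == 0 and len(r.rmsecv_trace) == 1
    # the returned subset is the best of the (only) bootstrap batch
    assert r.rmsecv_trace[0] == r.rmsecv_trace.min()


def test_boss_determinism_and_recovery():
    X, y, info, _ = synth.planted_cohort(seed=6)
    kw = dict(max_lv=10, n_iterations=8, n_bootstrap_models=40, cv_folds=5, seed=6)
    r1 = boss(X, y, **kw)
    r2 = boss(X, y, **kw)
    np.testing.assert_array_equal(r1.chosen, r2.chosen)
    assert _hits(r1.chosen, info) == 5


def test_selected_subsets_improve_on_full_spectrum_majority():
    """Selection should not hurt: PLSR RMSECV on the chosen subset beats the
    full matrix in most seeds, for each selector."""
    from thzash._pls import rmsecv_by_lv

    # SPA is excluded: its OLS-scored chains keep so few variables that they
    # cannot beat full-band PLS noise averaging on this cohort — its known
    # weakness with collinear informative neighborhoods.
    wins = {"CARS": 0, "BOSS": 0, "GA": 0}
    seeds = range(5)
    for seed in seeds:
        X, y, info, _ = synth.planted_cohort(seed=seed)
        full = rmsecv_by_lv(X, y, 10, 5, seed)[0].min()

        def score(chosen):
            return rmsecv_by_lv(X[:, chosen], y, 10, 5, seed)[0].min()

        wins["CARS"] += score(cars(X, y, CarsConfig(n_runs=30, cv_folds=5,
                                                    seed=seed)).chosen) <= full
        wins["BOSS"] += score(boss(X, y, max_lv=10, n_iterations=8,
                                   n_bootstrap_models=40, cv_folds=5,
                                   seed=seed).chosen) <= full
        wins["GA"] += score(ga_select(X, y, pop_size=16, n_generations=10,
                                      cv_folds=5, seed=seed).chosen) <= full
    for method, w in wins.items():
        assert w >= 4, f"{method}: {w}/5"
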
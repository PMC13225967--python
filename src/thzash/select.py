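"""Characteristic-wavelength selection: SPA, CARS, GA and BOSS.

All four selectors consume calibration rows only and return a
:class:`SelectionResult` with the chosen frequency indices and the
diagnostic traces (per-iteration RMSECV, variable counts) used to plot
selection trajectories.

* SPA  — successive projections: greedy orthogonal-projection chains from
  every starting variable, scored by cross-validated OLS error; fully
  deterministic.
* CARS — competitive adaptive reweighted sampling: Monte Carlo PLS runs
  with an exponentially decaying enforced-retention ratio
  r_i = a*exp(-k*i), a = (p/2)^(1/(N-1)), k = ln(p/2)/(N-1) (run 1 keeps
  all p variables, run N keeps 2), followed by adaptive reweighted sampling
  with probability proportional to normalized |PLS coefficients|; the run
  subset with minimum RMSECV wins.
* GA   — binary-chromosome genetic algorithm (tournament selection,
  single-point crossover, bit-flip mutation, elitism of 1) with fitness
  = -RMSECV; after the last generation, variables whose selection frequency
  across the population falls inside a [lower, upper] window are retained.
* BOSS — bootstrapping soft shrinkage: weighted bootstrap variable
  sampling, PLS sub-models ranked by RMSECV, weights updated from the
  normalized |coefficients| of the best 10 % of sub-models; no variable is
  ever force-eliminated.

Tie-breaking everywhere resolves to the lowest variable index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pls import kfold_indices, pls1_fit, rmsecv_by_lv

__all__ = ["SelectionResult", "CarsConfig", "cars", "spa", "ga_select", "boss"]


@dataclass
class SelectionResult:
    method: str
    chosen: np.ndarray  # sorted variable indices
    chosen_freq_THz: np.ndarray | None
    rmsecv_trace: np.ndarray
    n_vars_trace: np.ndarray
    best_iteration: int
    seed: int | None
    diagnostics: dict = field(default_factory=dict)

    def to_json_dict(self):
        d = {
            "method": self.method,
            "chosen": self.chosen.tolist(),
            "rmsecv_trace": np.asarray(self.rmsecv_trace, float).tolist(),
            "n_vars_trace": np.asarray(self.n_vars_trace, int).tolist(),
            "best_iteration": int(self.best_iteration),
            "seed": self.seed,
        }
        if self.chosen_freq_THz is not None:
            d["chosen_freq_THz"] = [f"{f:.6f}" for f in self.chosen_freq_THz]
        return d


@dataclass(frozen=True)
class CarsConfig:
    n_runs: int = 100
    max_lv: int = 10
    cv_folds: int = 10
    mc_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.mc_fraction < 1:
            raise ValueError("mc_fraction must be in (0, 1)")


def _freqs(freq_THz, chosen):
    return None if freq_THz is None else np.asarray(freq_THz, float)[chosen]


def _subset_rmsecv(X, y, subset, max_lv, folds, cv_seed):
    r, _ = rmsecv_by_lv(X[:, subset], y, max_lv, folds, cv_seed)
    return float(r.min()), int(np.argmin(r)) + 1


def cars(X, y, config: CarsConfig = CarsConfig(), freq_THz=None):
    """Competitive adaptive reweighted sampling over the calibration matrix."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("CARS needs at least 3 variables")
    N = config.n_runs
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    # Monte Carlo stream is separate from the inner-CV fold seed so that
    # selector comparisons at the same seed share fold assignments.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    cv_seed = config.seed
    n_mc = max(2, int(round(config.mc_fraction * n)))

    retained = np.arange(p)
    subsets, rmsecv_trace, n_vars_trace = [], [], []
    for i in range(1, N + 1):
        rows = np.sort(rng.choice(n, size=n_mc, replace=False))
        rme, lv = _subset_rmsecv(
            X[rows], y[rows], retained, config.max_lv, config.cv_folds, cv_seed
        )
        fit = pls1_fit(X[rows][:, retained], y[rows], lv)
        b = fit.B[:, min(lv, fit.n_components) - 1]
        w = np.abs(b)
        if w.sum() <= 0:
            w = np.ones_like(w)
        w = w / w.sum()
        keep_n = int(np.ceil(a * np.exp(-k * i) * p))
        keep_n = min(keep_n, retained.size)
        if keep_n < 2:
            break
        # enforced elimination: keep the keep_n largest weights (stable order)
        order = np.argsort(-w, kind="stable")[:keep_n]
        enforced = retained[np.sort(order)]
        w_enf = w[np.sort(order)]
        w_enf = w_enf / w_enf.sum()
        # adaptive reweighted sampling: resample keep_n draws, keep uniques
        draws = rng.choice(enforced.size, size=keep_n, replace=True, p=w_enf)
        retained = np.unique(enforced[draws])
        if retained.size < 2:
            break
        rme_full, _ = _subset_rmsecv(
            X, y, retained, config.max_lv, config.cv_folds, cv_seed
        )
        subsets.append(retained.copy())
        rmsecv_trace.append(rme_full)
        n_vars_trace.append(retained.size)

    rmsecv_trace = np.asarray(rmsecv_trace)
    best = int(np.argmin(rmsecv_trace))
    chosen = np.sort(subsets[best])
    return SelectionResult(
        "CARS",
        chosen,
        _freqs(freq_THz, chosen),
        rmsecv_trace,
        np.asarray(n_vars_trace),
        best,
        config.seed,
        {"edf_a": a, "edf_k": k},
    )


def _ols_oof_rmse(X, y, folds_ix):
    """RMSECV of an OLS-with-intercept fit over precomputed folds."""
    oof = np.empty_like(y)
    for train, test in folds_ix:
        A = np.column_stack([np.ones(train.size), X[train]])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        oof[test] = np.column_stack([np.ones(test.size), X[test]]) @ coef
    return float(np.sqrt(np.mean((oof - y) ** 2)))


def spa(X, y, k_min=1, k_max=None, cv_folds=10, freq_THz=None):
    """Successive projections algorithm; deterministic (folds seeded at 0).

    Builds, from every starting variable, a chain that repeatedly adds the
    variable with the largest norm after projection onto the orthogonal
    complement of the chain's span (projections on the raw column vectors, as
    in the classical formulation), then scores every (start, k) subset for
    k in [k_min, k_max] by cross-validated OLS error and returns the best.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if k_max is None:
        k_max = min(n - 2, p, 20)
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > min(n - 1, p):
        raise ValueError("k_max must be <= min(n-1, p)")
    Xc = X
    folds_ix = kfold_indices(n, min(cv_folds, n), 0)

    chains = []
    for start in range(p):
        R = Xc.copy()
        chain = [start]
        for _ in range(k_max - 1):
            v = R[:, chain[-1]].copy()
            nv = v @ v
            if nv < 1e-24:
                break
            R -= np.outer(v, (v @ R) / nv)
            norms = np.einsum("ij,ij->j", R, R)
            norms[chain] = -1.0
            nxt = int(np.argmax(norms))
            if norms[nxt] < 1e-24:
                break  # rank collapse: chain truncated
            chain.append(nxt)
        chains.append(chain)

    # numerically tied scores (differences far below any meaningful error
    # scale) resolve to the smaller subset, then the lower starting variable
    tol = 1e-9 * max(float(np.std(y)), 1e-30)
    best = None  # (rmsecv, start, k)
    trace, nvars = [], []
    for start, chain in enumerate(chains):
        for kk in range(k_min, min(k_max, len(chain)) + 1):
            r = _ols_oof_rmse(X[:, chain[:kk]], y, folds_ix)
            trace.append(r)
            nvars.append(kk)
            if best is None or r < best[0] - tol or (r < best[0] + tol and kk < best[2]):
                best = (r, start, kk)
    r, start, kk = best
    chosen = np.sort(np.asarray(chains[start][:kk]))
    trace = np.asarray(trace)
    return SelectionResult(
        "SPA",
        chosen,
        _freqs(freq_THz, chosen),
        trace,
        np.asarray(nvars),
        int(np.argmin(trace)),
        None,
        {"start": start, "k": kk},
    )


def ga_select(
    X,
    y,
    pop_size=30,
    n_generations=30,
    p_crossover=0.8,
    p_mutation=0.02,
    freq_lower=0.3,
    freq_upper=1.0,
    seed=0,
    max_lv=10,
    cv_folds=10,
    init_prob=0.3,
    freq_THz=None,
):
    """Genetic-algorithm wavelength selection with a frequency-window filter."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be even and >= 4")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    cv_seed = seed

    def fitness(chrom):
        idx = np.nonzero(chrom)[0]
        if idx.size < 1:
            return np.inf
        r, _ = _subset_rmsecv(X, y, idx, max_lv, cv_folds, cv_seed)
        return r

    pop = rng.random((pop_size, p)) < init_prob
    for c in pop:
        if not c.any():
            c[rng.integers(p)] = True
    scores = np.array([fitness(c) for c in pop])
    trace, nvars = [], []
    for _ in range(n_generations):
        elite = pop[int(np.argmin(scores))].copy()
        new = []
        while len(new) < pop_size:
            # tournament selection, size 2 (lower RMSECV wins)
            pick = rng.integers(pop_size, size=4)
            pa = pop[pick[0] if scores[pick[0]] <= scores[pick[1]] else pick[1]]
            pb = pop[pick[2] if scores[pick[2]] <= scores[pick[3]] else pick[3]]
            c1, c2 = pa.copy(), pb.copy()
            if rng.random() < p_crossover:
                cut = rng.integers(1, p)
                c1[cut:], c2[cut:] = pb[cut:].copy(), pa[cut:].copy()
            for c in (c1, c2):
                flip = rng.random(p) < p_mutation
                c[flip] = ~c[flip]
            new.extend([c1, c2])
        pop = np.array(new[:pop_size])
        pop[0] = elite  # elitism of 1
        scores = np.array([fitness(c) for c in pop])
        trace.append(float(scores.min()))
        nvars.append(int(pop[int(np.argmin(scores))].sum()))

    sel_freq = pop.mean(axis=0)
    retained = np.nonzero((sel_freq >= freq_lower) & (sel_freq <= freq_upper))[0]
    diagnostics = {"selection_frequency": sel_freq}
    if retained.size == 0:
        retained = np.nonzero(pop[int(np.argmin(scores))])[0]
        diagnostics["fallback"] = "empty frequency window; using best chromosome"
    trace = np.asarray(trace)
    return SelectionResult(
        "GA",
        np.sort(retained),
        _freqs(freq_THz, np.sort(retained)),
        trace,
        np.asarray(nvars),
        int(np.argmin(trace)),
        seed,
        diagnostics,
    )


def boss(
    X,
    y,
    max_lv=20,
    n_iterations=2000,
    n_bootstrap_models=100,
    seed=0,
    cv_folds=10,
    stall_tol=1e-3,
    stall_window=10,
    freq_THz=None,
):
    """Bootstrapping soft shrinkage.

    Variable weights start equal; each iteration draws ``n_bootstrap_models``
    subsets by weighted bootstrap sampling (p draws with replacement,
    deduplicated), fits PLS sub-models ranked by RMSECV, and replaces the
    weights with the normalized sum of |coefficients| over the best 10 % of
    sub-models.  Iterates until ``n_iterations`` or until the expected subset
    size E = sum_j (1-(1-w_j)^p) changes by < ``stall_tol`` (relative) over
    ``stall_window`` iterations.  Returns the sub-model subset with the
    global minimum RMSECV.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("BOSS needs at least 3 variables")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    cv_seed = seed
    w = np.full(p, 1.0 / p)
    n_top = max(1, int(np.ceil(0.1 * n_bootstrap_models)))

    best = None  # (rmsecv, subset)
    trace, nvars, esize_hist = [], [], []
    for it in range(n_iterations):
        if w.sum() <= 0 or not np.isfinite(w).all():
            raise RuntimeError(f"all variable weights vanished at iteration {it}")
        results = []
        for _ in range(n_bootstrap_models):
            subset = np.unique(rng.choice(p, size=p, replace=True, p=w))
            if subset.size < 1:
                continue
            r, lv = _subset_rmsecv(X, y, subset, max_lv, cv_folds, cv_seed)
            results.append((r, lv, subset))
        results.sort(key=lambda t: t[0])
        it_best = results[0]
        if best is None or it_best[0] < best[0] - 1e-15:
            best = (it_best[0], it_best[2])
        trace.append(it_best[0])
        nvars.append(it_best[2].size)
        # soft shrinkage: accumulate |coefficients| of the top 10 % sub-models
        acc = np.zeros(p)
        for r, lv, subset in results[:n_top]:
            fit = pls1_fit(X[:, subset], y, lv)
            acc[subset] += np.abs(fit.B[:, min(lv, fit.n_components) - 1])
        if acc.sum() <= 0:
            raise RuntimeError(f"all variable weights vanished at iteration {it}")
        w = acc / acc.sum()
        esize = float(np.sum(1.0 - (1.0 - w) ** p))
        esize_hist.append(esize)
        if len(esize_hist) > stall_window:
            ref = esize_hist[-stall_window - 1]
            if abs(esize - ref) / max(ref, 1e-12) < stall_tol:
                break

    chosen = np.sort(best[1])
    trace = np.asarray(trace)
    return SelectionResult(
        "BOSS",
        chosen,
        _freqs(freq_THz, chosen),
        trace,
        np.asarray(nvars),
        int(np.argmin(trace)),
        seed,
        {"final_weights": w, "expected_subset_size": esize_hist},
    )
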
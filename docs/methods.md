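# Methods

## The measurement model

Transmission THz-TDS records the electric field `E(t)` of a single-cycle
picosecond pulse after passing through a pressed wheat-flour/polyethylene
pellet of thickness `d`, and the same pulse through the empty (reference)
path. In the frequency domain the pellet multiplies the reference spectrum
by a transfer function

    H(ν) = exp(-α(ν)·d/2) · exp(-2πiν·(n_eff-1)·d/c),

i.e. field attenuation by half the intensity absorption coefficient `α`
(cm⁻¹) and a group delay from the effective refractive index `n_eff`. The
first-pass thin-pellet inversion used throughout is

    n(ν) = 1 + c·Δφ(ν)/(2πν·d)
    α(ν) = (2/d)·ln[ρ(ν)·A_ref(ν)/A_samp(ν)],   ρ = 4n/(n+1)² or 1
    T(ν) = (A_samp/A_ref)²

with `Δφ` the unwrapped reference-minus-sample phase. Fabry–Pérot echoes,
dispersion and scattering-theory corrections are out of scope; the Fresnel
factor `ρ` is exposed but off by default, matching the generator (which
applies no interface loss), and the formulas are isolated in `optics` so a
different inversion can be substituted.

Phase unwrapping is anchored at the low-frequency end of the usable band: a
line through the lowest ~40 frequencies where the reference magnitude
exceeds 20 % of its peak is extrapolated to ν = 0 and the nearest multiple
of 2π subtracted. Anchoring on *strong* bins matters: the synthetic (and
real) noise floor rises steeply at the lowest frequencies, and unwrap
glitches there would otherwise shift whole spectra by 2π branches —
visible as refractive-index outliers of ±c/(νd) ≈ ±0.3.

Replicates are averaged in the complex spectral domain before any parameter
extraction, so incoherent noise cancels while a consistent phase is kept.

## The synthetic cohort

The generator emulates the study conditions: 183 samples, three cultivars
in equal proportion, reference ash drawn uniformly in 0.36–0.71 %, pellet
thickness uniform in 1.2 ± 0.5 mm, three replicate traces per sample,
spectra on a 0.1–4.5 THz grid (step 0.0125 THz). The pulse is a
first-derivative Gaussian (width 0.2 ps, zero DC); the absorption model is
linear in ash with Gaussian bands,

    α(ν; ash) = baseline + Σ_b (s0_b + slope_b·ash)·G(ν; c_b, w_b),

with four ash-sensitive bands at 0.30/0.55/0.80/1.05 THz (slopes 22–30
cm⁻¹ per % ash) — the region where mineral phonon/collective modes live —
plus one ash-insensitive decoy band at 2.0 THz. `n_eff` is constant
(default 1.5, non-dispersive), so delay is frequency-independent.

Noise model, all scaled by one `noise_sd` (default 7·10⁻⁴ a.u.):

* white noise per time sample, per replicate;
* a low-frequency drift pedestal (delay-line/baseline drift), spectral
  amplitude 45× the white floor at 0.1 THz decaying with scale 0.02 THz —
  this is what makes the SNR screen drop the low grid edge, as the severe
  low-frequency noise of real systems does;
* a per-sample scattering ramp `s_i·ν` with `s_i ~ N(2, 1)` cm⁻¹/THz
  clipped at 0 (particle-size/packing variation — the effect MSC and SNV
  exist to correct);
* a caliper error of sd 0.02 mm between true and recorded thickness.

The defaults put the extracted-absorption signal-to-noise ratio at the
mineral band centers near 20 (ash-signal sd over noise sd, after replicate
averaging). `CohortConfig.noiseless()` zeroes all four terms for exact
round-trip checks. Per-sample random streams are derived from the master
seed by counter, so cohort content is independent of generation order.

The separate `planted_cohort` fixture serves the selector tests: 200
abstract variables, five informative Gaussian bands, one high-variance
ash-insensitive decoy, noise 1× at band centers rising to 6× far from them,
and a smooth structured artifact region over the top 15 % of indices
(emulating the dynamic-range collapse at high frequency). The structure is
what makes variable selection *pay*: with homoscedastic white noise alone,
PLS simply down-weights uninformative columns and full-spectrum models are
never beaten, which would make every selection benchmark vacuous.

What passing tests on this surface do **not** show: real flour spectra have
correlated chemistry (protein/starch/moisture absorption), etalon fringes,
humidity lines and instrument drift none of which are modeled; recovery
rates and prediction metrics here certify the algorithms, not field
performance.

## Valid-band screening

The screen computes, per frequency, the mean reference magnitude over the
noise floor in dB (floor = sd across replicate reference spectra, or the
replicate scatter of the sample spectra averaged over samples when only one
reference trace exists) and keeps the longest contiguous run ≥ 10 dB. One
mask is applied to all four datasets. An empty result raises; it is never a
silent empty matrix.

## Preprocessing

"3-point average" smoothing is implemented as Savitzky–Golay window 3,
polyorder 1, which equals the moving average on interior points; window 3
with polyorder 2 would be the identity and could smooth nothing.
Derivatives default to window 5, polyorder 2, in per-THz units. SNV scales
each spectrum by its own sd; rows with sd < 1e-12 are set non-finite and
reported per row — the division is meaningless and hiding it would let NaNs
reach a model. MSC regresses each spectrum on a reference spectrum (the
calibration-set mean, frozen and reused for prediction rows — never
re-estimated). Preprocessing operates on valid-band columns, after
screening.

## Partitioning

Kennard–Stone maximin selection runs on spectra (uniform coverage of
spectral space), with the deterministic tie rule "lowest row index". The
calibration size is the nearest integer to `n·ratio/(ratio+1)` globally,
allocated to cultivar strata by largest remainder — per-stratum rounding
would not reproduce 137/46 for all stratum compositions. Outliers are
flagged by quartile-based Tukey fences (linear-interpolation quartiles) and
retained. The t-test is pooled by default (Welch optional).

## Selectors

All selectors see calibration rows only, and share inner-CV fold
assignments at a given seed (the fold stream is independent of each
selector's Monte Carlo stream).

* **CARS** (defaults: 100 Monte Carlo runs, max 10 LVs, 10-fold CV,
  0.8 row sampling): enforced retention follows the exponential decay
  `r_i = a·e^{-k·i}` with `a, k` fixed by `r_1·p = p`, `r_N·p = 2`;
  adaptive reweighted sampling draws with probability ∝ normalized |PLS
  coefficients|; each run's subset is scored by RMSECV on the full
  calibration set (the subset-scoring convention is a choice; the
  Monte-Carlo-subset alternative is not implemented).
* **SPA**: orthogonal-projection chains on raw column vectors from every
  start, scored by cross-validated OLS; numerically tied scores (within
  1e-9·sd(y)) resolve to the smaller subset, then the lower start — needed
  so a noiseless case recovers the exact support rather than a
  floating-point-tied superset.
* **GA** (defaults: population 30, 30 generations, crossover 0.8, per-bit
  mutation 0.02, init probability 0.3): tournament selection, single-point
  crossover, elitism 1; after the last generation variables with selection
  frequency in [0.3, 1.0] are retained (the window bounds are exposed; an
  empty window falls back to the best chromosome, logged in diagnostics).
* **BOSS** (defaults: max 20 LVs, iteration cap 2000 with an early stop
  when the expected subset size `Σ_j (1-(1-w_j)^p)` changes < 0.1 % over 10
  iterations, 100 bootstrap sub-models per iteration): weighted bootstrap
  subsets, sub-models ranked by RMSECV, weights rebuilt from the top 10 %
  sub-models' |coefficients| — soft shrinkage, no forced elimination.

Known limitation: SPA's chains rank variables by projection norm alone, so
high-variance junk regions must be screened out before it runs, and its
2–8-variable OLS-scored subsets cannot beat full-band PLS noise averaging
on cohorts whose informative bands are collinear neighborhoods; the
"selection never hurts" majority property therefore holds for CARS, BOSS
and GA but is not claimed for SPA.

## Models and cross-validation

PLS1 is NIPALS on column-centered data, single response, no y-deflation;
coefficients for every LV truncation come from one pass
(`B_a = W_a(P_a'W_a)^{-1}q_a`, with `P'W` unit upper triangular). PLSR picks
the LV count minimizing out-of-fold RMSECV. PLSR/MLR/PCR center columns but
do not scale (absorption spectra share units); SVR z-scores internally and
fixes ε = 0.01·sd(y). MLR *refuses* designs with p ≥ n or a centered
cross-product condition number above 1e10 — the guard against
multicollinearity is a contract, not a warning. PCR keeps the smallest k
with cumulative explained variance ≥ 95 % (CV-chosen k is not the default
reading of the rule and is not implemented). The SVR grid is exhaustive
over integer exponents (16 × 16 = 256 candidates), ties to smaller C then
smaller γ.

Cross-validation assembles out-of-fold predictions over all calibration
rows with seeded, shuffled folds; centering, scaling, the PLSR LV count and
the PCR component count are refit inside each fold. One deliberate
exception: SVR's (C, γ) pair is chosen once on the calibration set and only
its coefficients and scaling are refit per fold — re-running the 256-point
grid search inside every fold multiplies cost tenfold for a near-identical
choice, and prediction-set metrics are unaffected either way.

## Evaluation

Rc and Rp are the coefficient-of-determination forms
`1 − SSres/SStot` with the respective set's own reference mean; because the
label "correlation coefficient" is ambiguous in the chemometrics
literature, a plain Pearson r is carried alongside. Calibration predictions
are out-of-fold CV predictions by default (`rc_mode="insample"` switches to
refit predictions). `SD_pred` uses the sample (m−1) convention. RPD =
SD_pred/RMSEP, reported as +∞ when RMSEP = 0; grades are lower-inclusive at
1.5/2.0/2.5. R-form values never exceed 1 and may be negative for
worse-than-mean predictors.

`run_pipeline` sweeps the cross product of preprocess × selector × model,
enforces split-before-statistics, runs selectors on calibration rows only,
and converts any non-finite feature matrix into an explicit recorded
refusal (no metrics row) rather than NaN output. Reports are byte-stable
for a fixed config and seed. The split distances use the first
row-independent preprocessing of the sweep; MSC (a cross-sample operator)
falls back to raw spectra for distances to avoid leakage.

## Problem sizes and numerical choices

* Default tests and the acceptance script scale the stochastic studies to
  desk size, chosen as the smallest runs whose majority properties are
  stable: selector benchmarks use 20 seeds of the 120 × 200 planted cohort
  with CARS at 50 Monte Carlo runs and BOSS at a 20-iteration cap with 60
  sub-models and 5-fold ranking; the pipeline study uses 10 seeds of the
  full 183-sample cohort with CARS at 50 runs.
* The time grid is derived from the frequency grid (Nyquist ≥ 8 THz,
  1280 samples of 0.0625 ps), so the instrument grid is an exact subset of
  the FFT grid and round-trips are limited only by floating point.
* Degenerate inputs raise typed errors: fewer than 16 grid points,
  non-uniform time axes (naming the offending step), empty screened bands,
  zero-variance responses, singleton strata.
* Tie-breaks are deterministic everywhere (first minimum / lowest index),
  making every selector reproducible from its seed; SPA is fully
  deterministic.

## Known limitations

* The SVR grid includes γ = 2⁻¹⁰, a quasi-linear RBF limit; on linearly
  generated spectra SVR therefore matches the linear models instead of
  overfitting as it does on real flour data, and no strict
  PLSR > MLR > SVR > PCR ordering is claimed — the asserted orderings are
  PLSR ≥ PCR (majority over seeds) and PLSR reaching the "excellent" grade.
* The forward model is non-dispersive and single-pass; refractive-index
  spectra carry no structure beyond `n_eff` plus noise, so models built on
  them are only a negative control.
* Reference measurements are modeled as the unmodified pulse (air path); a
  blank-PE-pellet reference option is not implemented.
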
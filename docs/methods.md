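# Methods

## The model

`neurosgm` implements a spectral graph model (SGM) of resting-state brain
activity: a linear, deterministic model that predicts the power spectrum of
every cortical region in closed form from (i) a structural connectome and
(ii) seven global, spatially invariant biophysical parameters. Each region
hosts a linearized circuit of one excitatory and one inhibitory neural
ensemble; the excitatory populations of different regions are coupled
through the anatomical network with conduction delays. Because the model is
linear it is solved entirely in the frequency domain — no time-domain
simulation is involved anywhere in the fitting path.

### Local circuit

Each ensemble's impulse response is the normalized gamma kernel
`h(t) = t/τ² · exp(−t/τ)`, whose transfer function is the squared
first-order low-pass

    F(ω) = 1 / (1 + jωτ)²,   F(0) = 1.

The local circuit couples the two populations with gains `g_ee` (excitatory
self-damping, fixed at 1 and not optimized), `g_ei` (the alternating
excitatory–inhibitory loop gain) and `g_ii` (inhibitory self-gain):

    jω X_e = −(F_e/τ_e)(g_ee X_e + g_ei X_i) + P
    jω X_i = −(F_i/τ_i)(g_ii X_i − g_ei X_e) + P

Solving this 2×2 system for the total local response `H_local = (X_e+X_i)/P`
gives a rational transfer function whose denominator

    Δ(ω) = (jω + g_ee F_e/τ_e)(jω + g_ii F_i/τ_i) + g_ei² F_e F_i/(τ_e τ_i)

carries the local resonance through the `g_ei²` loop term. The algebra is
verified in the tests against an independent 6-state state-space realization
of the same circuit (each gamma kernel as a critically damped second-order
filter), via `scipy.signal.freqresp`.

### Network level

Long-range coupling enters through a frequency-dependent complex Laplacian

    L(ω) = I − α · N(C ∘ exp(−jω D / v')),

where `C` is the connectivity matrix, `D` the fiber-distance matrix in mm,
`v'` the conduction speed in mm/s, `α` the global coupling constant, and
`N(·)` row-degree normalization by the (real) row sums of `C`. Rows of `C`
with zero degree stay zero (normalizing an isolated node is undefined), and
self-connections are zeroed on load. At `f → 0` the Laplacian reduces to
the real matrix `I − α·N(C)`.

The steady-state regional response is

    X(ω) = Σ_k  u_k v_kᴴ P(ω) H_local(ω) / (jω + λ_k F_G(ω)/τ_G),

with `(λ_k, u_k, v_k)` the right/left eigenpairs of `L(ω)` (biorthogonally
normalized — `L` is not normal, so the spectral projectors need the dual
eigenvectors), `F_G` the long-range gamma filter with time constant `τ_G`,
and `P(ω)` the per-region drive (unit white drive by default, pluggable).
At full truncation `K = N` the sum equals the resolvent solve
`(jωI + F_G/τ_G · L)⁻¹ H_local P`, which is the default evaluation path
(batched complex solves over the frequency grid); the eigenmode route is
kept for truncation experiments and falls back to a direct solve with a
logged warning if the eigendecomposition fails. Modes are ordered by
ascending |λ| so small `K` keeps the smoothest network modes. Power is
reported as `20·log10|X|` dB with a −300 dB floor for exact zeros.

Default frequency grid: 1–35 Hz at 0.25 Hz spacing; when fitting empirical
spectra the model is evaluated exactly on the empirical bins. All public
interfaces take Hz; `ω = 2πf` is derived inside `FrequencyGrid`.

### Parameters, units and bounds

| name | meaning | unit | optimization bounds |
|------|---------|------|--------------------|
| τ_e | local excitatory time constant | s | [0.005, 0.03] |
| τ_i | local inhibitory time constant | s | [0.005, 0.2] |
| τ_G | long-range (graph) excitatory time constant | s | [0.005, 0.03] |
| g_ei | alternating E–I gain | – | [0.001, 0.7 / 0.5 / 0.4] |
| g_ii | inhibitory gain | – | [0.001, 2.0 / 1.5 / 1.5] |
| α | global coupling | – | [0.1, 1] |
| v | conduction speed | m/s | [5, 20] |

Internally everything is SI (seconds); reported tables convert time
constants to milliseconds. The gain bounds shrink over three stages
(slashes above) — see stability below. Three fixed initial guesses span the
box; they are part of the fitting contract, not tunable state.

## Stability

Within the stage-1 box a minority of gain/time-constant combinations yield
an unbounded circuit. `stability_check` declares a parameter set stable iff
(a) the gains lie inside the requested stage's bounds, and (b) the response
is bounded: the determinant magnitude `|Δ(ω)|` stays above 1e−6 on a dense
0.1–100 Hz grid *and* all roots of the circuit's characteristic polynomial

    (s(1+sτ_e)² + g_ee/τ_e)(s(1+sτ_i)² + g_ii/τ_i) + g_ei²/(τ_e τ_i)

have negative real part. The polynomial criterion is the exact boundedness
condition for this circuit; the frequency scan alone cannot detect a pole
that sits in the right half plane away from the real-frequency axis. Tests
validate the verdict against a time-domain integration of the state-space
realization.

## Subject-level inference

The objective maximized per subject is the sum of two scale-free terms:

* **spectral correlation** — Pearson r between modeled and empirical dB
  spectra, computed per region across frequencies and averaged over regions
  (constant-spectrum regions are excluded with a warning);
* **spatial correlation** — `x̃ᵀ M ỹ / N`, where `x̃, ỹ` are the regional
  alpha-band (8–12 Hz, trapezoid on linear power) maps of model and data,
  z-scored across regions with the population SD, and
  `M = rownorm(N(C) + w I)` with `w = 10`. With `C = 0` this reduces to
  Pearson r; on a connected graph the smoothing makes even the
  self-correlation slightly less than 1 (typically 0.88–0.95 on the
  synthetic graphs), so a perfect noiseless fit tops out near 1.9–1.95
  rather than 2.

Optimization is `scipy.optimize.dual_annealing` (maxiter 500 by default)
over the bound box rescaled to the unit cube for conditioning, run from
each of the three initial guesses. Unstable parameter sets receive a
traversable penalty value (−10) instead of an exception. If a stage's
optimum fails the stability check the fit is re-run under the stage-2, then
stage-3 gain bounds; the best stable result across guesses wins, ties going
to the lowest guess index. Everything is deterministic given the seed;
cohort fits derive per-subject seeds from the subject id (CRC32), so batch
results are independent of iteration order and resumable from cached
per-subject JSON.

The fit matches spectral *shape*, not magnitude (Pearson r is offset- and
scale-free); no uncertainty quantification is attempted.

## Cohort layer

* **Group comparison** — the study design has one observation per subject,
  so the mixed model reduces to a fixed-effects linear model
  `parameter ~ group + age`. Adjusted (least-squares) means are evaluated
  at the pooled mean age with 95% CIs (level config-exposed); the group
  contrast is the t-test on the group coefficient, Bonferroni-corrected
  over the seven-parameter family (m = 7). Cohen's d (pooled SD, n−1
  denominators) is computed on the raw values. Constant age falls back to
  an unadjusted comparison with a warning.
* **Cognition regressions** — OLS on patient rows: univariate models per
  parameter and a multivariate model with age, Bonferroni over the number
  of parameters tested. Reported: slopes, raw/adjusted p, model r,
  adjusted r², F.
* **Classification** — random forest (100 trees by default; the tree count
  is not part of the contract and is config-exposed) under nested
  stratified CV: outer 5-fold repeated `repeats` times (default 100), inner
  5-fold grid search tuning only `max_depth ∈ {None, 2, 3, 4}`. Tuning
  never sees the held-out fold. AUROC is computed per repeat on pooled
  outer-fold scores; importances are impurity-based, averaged over all
  tuned forests and renormalized to sum to 1. The inner fold count clamps
  to the training-split class size so tiny cohorts remain runnable.
* **Ablation** — starting from all seven parameters clamped to the pooled
  cohort mean of the fitted values, parameters are freed one at a time in
  classifier-importance order and each subject re-fit over the freed subset
  only (same staged optimizer, same per-subject seeds). The free subset is
  canonicalized to a fixed dimension order, so the all-free stage
  reproduces independent full fits bit-for-bit under shared seeds.

## Spectral features

Empirical spectra come from Welch's method (2 s Hann windows, 50% overlap;
a raw periodogram mode is provided), interpolated onto the analysis grid
and converted to dB. The intrinsic timescale is the lag at which the
region-averaged normalized autocorrelation first decays to 1/e, with linear
interpolation between discrete lags; the estimator takes the series as
given — bandpass filtering (1–35 Hz zero-phase Butterworth, order 4
effective 8) is a separate pipeline step, because filtering inside the
estimator would distort the analytic AR(1) fixtures used to validate it.
Traces that never reach 1/e within the lag window are returned with a
censored flag. The peak parameterization is deliberately simplified
relative to full spectral-parameterization toolboxes: a robust (soft-L1)
fit of `offset − exponent·log10 f`, then greedy Gaussian fits to residual
maxima above 2 residual SDs, at most 6 peaks, no knee mode and no overlap
resolution.

## Synthetic data

The generators define the study conditions for every test:

* **Connectome** — N points on a 70 mm sphere with hemispheric mirror
  symmetry; D = Euclidean distances; `C ∝ exp(−D/30 mm)` with symmetric
  lognormal jitter (σ = 0.5). This reproduces the distance decay and
  bilateral symmetry of real connectomes but none of their community
  structure or hub topology.
* **Subject spectra** — forward model plus i.i.d. Gaussian noise in the dB
  domain (multiplicative in linear power, the scale the objective operates
  on); default SD 1 dB.
* **Time series** — per-region AR(1) with coefficient `exp(−1/(fs·τ))` and
  unit stationary variance; fs 600 Hz, 60 s by default, matching a
  one-minute resting recording.
* **Cohort** — two groups whose effect-carrying parameters (τ_G, τ_e, g_ii)
  have group means 7.50/13.90 ms, 11.88/15.01 ms and 0.26/0.46. Group SDs
  are back-derived from the reported effect sizes (gap/Cohen's D: 5.52 ms,
  7.63 ms, 0.476). Because those SDs are not jointly attainable with the
  target means under the optimization-bound truncation, the generator
  solves for the truncated-normal *location* such that the realized group
  means hit the targets exactly; realized SDs are therefore smaller and
  realized effect sizes larger than the printed ones. The ~5% of draws
  falling in the unstable tail of the box are rejection-resampled. Shared
  parameters center on the first initial guess with modest spreads
  (τ_i 10±2 ms, g_ei 0.3±0.05, α 1.0±0.1, v 5±2, truncated to bounds).
  Ages are Gaussian (65.07±9.92 control, 62.73±8.64 patients); MMSE =
  29.1 − 0.5·τ_G(ms) + ε(4.8), clipped to [0, 30], calibrated so the
  patient mean lands near 22.1; CDR = 2.1 + 0.2·τ_G(ms) + ε(2.5), clipped
  at 0. Cognition scores are generated for patients only. Null and
  τ_G-only effect modes exist for calibration experiments. All generators
  are pure functions of (spec, seed) on numpy's PCG64.

What passing tests on these data do *not* show: robustness to source
leakage, non-Gaussian measurement noise, individual connectome variation,
violations of spatial invariance, or any other structure of real MEG that
the generators omit.

## Pipeline

`run_pipeline(config, mode)` executes simulate → fit → analyze → classify →
ablate in dependency order (`all` runs the full set), writing a
self-contained run directory: echoed config with a content hash, dataset
(delimited text matrices and spectra, cohort CSV, ground-truth sidecar),
per-subject fit JSON plus a cohort CSV, and JSON + Markdown reports. In
simulate mode, per-subject AR(1) time series with target timescale
`5 · τ_G` feed the timescale stage of the analysis report; the factor is a
plumbing scale chosen so timescales land in a plausible 40–150 ms range,
not a modeling claim. Missing upstream artifacts raise a dependency error
naming the stage to run first. No timestamps enter reports, so identical
configs reproduce identical bytes.

## Problem sizes used in the checks

The reference cohort is private, so all quantitative checks run on
synthetic data at desk scale, chosen as the smallest sizes at which each
property is sharply testable: forward-model exactness on 54 random draws
over 4/8/16-region graphs; parameter recovery on 20 noisy subjects
(16-region graph, dual annealing maxiter 100); timescale recovery over 50
seeds × 3 timescales; statistical calibration over 500 null and 100
alternative cohorts of 40+40; classifier sanity on 40+40 cohorts (20
repeats for the null, 5 for the separable case); ablation on 5 subjects
over a 10-region graph at maxiter 25. The acceptance script
(`scripts/acceptance.py`) re-runs the same computations from scratch under
a caller-supplied seed.

## Known limitations

* The exact algebraic variant of the local circuit and the Laplacian
  normalization differ across the SGM literature; the ones here are fixed
  by the contracts above and verified against independent oracles, but are
  not guaranteed to match any particular published code line-for-line.
* `g_ee` is fixed at 1 by convention; it trades off against the overall
  response scale, which the scale-free objective cannot identify anyway.
* The spatial-correlation statistic is not a true correlation on connected
  graphs (self-similarity < 1); it is used exactly as defined by the
  fitting contract.
* Dual annealing at reduced maxiter is stochastic in its exploration;
  recovery guarantees are rank-based (Spearman) rather than pointwise.
* The simplified peak parameterization under-resolves overlapping peaks and
  has no aperiodic knee; it is adequate for the well-separated synthetic
  bumps it is tested on.
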
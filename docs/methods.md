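# Methods

## The lineage-statistics framework

`lineagestat` analyses growing cell populations through the ensemble of
*lineages*: the history of each cell present at the end of an observation
window `[t_start, t_end]`, traced back to its ancestor at the window start.
Each lineage σ carries its division count `D(σ)` and any scalar lineage
traits `X(σ)` (e.g. a time-averaged fluorescence level).

Two probability measures are placed on the same lineage set:

- **chronological** `P_cl(σ) = 2^(−D(σ))/N0` — the chance of reaching σ by
  walking down the tree from a random founder, choosing one of the two
  daughters with probability 1/2 at every division; the population as it
  would look *without* selection;
- **retrospective** `P_rs(σ) = 1/Nτ` — uniform over the lineages that
  actually survive; the population *after* selection.

Binning a trait under both measures gives the pair `Q_cl(x), Q_rs(x)`, from
which everything else follows:

- fitness landscape `h(x) = τΛ + ln(Q_rs(x)/Q_cl(x))`, with
  `τΛ = ln(Nτ/N0)`;
- selection strengths `S_KL1 = D_KL(Q_cl‖Q_rs) = τΛ − ⟨h⟩_cl`,
  `S_KL2 = D_KL(Q_rs‖Q_cl) = ⟨h⟩_rs − τΛ`, `S_JF = S_KL1 + S_KL2`;
- the cumulant generating function
  `K_X(ξ) = ln Σ_x e^(ξh(x)) Q_cl(x)`, whose endpoints/derivatives encode
  every quantity above, and whose Taylor coefficients κ_n give the cumulant
  expansion `τΛ = Σ_n κ_n/n!` with cumulative contributions
  `W_n = (1/τΛ) Σ_{k≤n} κ_k/k!`;
- the removal-perturbation response `Λ(ε) = K_D(1−ε)/τ` with initial
  relative slope `−(1 + S_KL2[D]/τΛ)`.

For isolated mother-machine lineages (no tree), the observed lineages are
chronological samples: `P_cl = 1/N0`, `P_rs ∝ 2^D`, and
`N̂τ = Σ 2^D` estimates the unobserved final cell count. All logarithms are
natural; fitness is reported in nats (the `--per-division` CLI option
rescales by ln 2, one nat-per-ln2 unit per division).

The framework assumes binary division, a complete tree over the window (or
a representative chronological sample), and nothing about the underlying
growth law. `h(x)` and the strengths measure *correlation* between trait
and reproductive success, not causation.

## Key conventions and parameters

- **Window convention.** A division at exactly `t_start` belongs to the
  previous window (open at the start, closed at the end:
  `t_start < t_div ≤ t_end`), so the cells present at `t_start` are exactly
  the `N0` founders. The input data do not dictate this choice; it is the
  only one that keeps the dyadic conservation law `Σ_σ 2^(−D) = N0`
  exact, which `LineageEnsemble.check_conservation` verifies in exact
  rational arithmetic.
- **Censored cells.** Every estimator assumes complete trees, so a lost
  cell inside the window is an error by default (`policy="strict"`);
  `policy="lenient"` drops the affected subtree, warns, and flags the
  broken conservation law on the ensemble.
- **Binning.** Division counts always get one bin per integer. Continuous
  traits default to the empirical width rule `ΔX = 0.4·IQR` with the
  linear-interpolation quartile convention (recorded in the output
  metadata); bins are half-open `[x − ΔX/2, x + ΔX/2)` anchored at the data
  minimum, which resolves the double counting a closed-interval definition
  would create at shared endpoints. Only occupied bins are kept, so the
  chronological and retrospective supports coincide by construction.
- **Cumulants** (`cumulants`, default `n_max = 20`) come from power-series
  arithmetic on the exact finite-support moment generating function: the
  raw-moment series of the *centered* landscape is log-transformed by the
  standard series recursion and the mean is restored into κ₁. Centering
  first matters: with an uncentered mean of order τΛ the recursion loses
  ~10 significant digits by n ≈ 20. The independent cross-check in the test
  suite uses the classical moment→cumulant recursion and the central-moment
  formulas (κ₃ = m₃c, κ₄ = m₄c − 3m₂c²). A series is marked `converged`
  when `|W_nmax − 1| < 1e-6` and the absolute tail has been decreasing over
  the last three orders; non-convergence is reported, never silently
  truncated.
- **Identity cross-checks.** `selection_strengths` evaluates both defining
  routes (divergence sums and mean-fitness differences) and raises if they
  disagree beyond 1e-10; binned masses are renormalized after accumulation
  (float summation over ~10⁶ lineages drifts by ~10⁻¹⁰) with a 1e-9 guard.
- **Relative selection strength** `S_rel[X] = S_KL1[X]/S_KL1[D]` uses the
  first Kullback-Leibler direction in both numerator and denominator. It
  lies in [0, 1] because the likelihood ratio `P_rs/P_cl` depends on σ only
  through D, making D a sufficient statistic: any trait binning is a
  further coarsening, and divergences can only shrink (this data-processing
  bound is fuzz-tested for all three measures). Finite data always give
  `S_rel > 0`, so significance is assessed with the permutation null
  (`randomization_null`): trait values are shuffled against division counts
  and the observed value is ranked in the permuted distribution. No
  analytic small-sample bias correction is attempted.

## The branching-process simulator

`simulate` implements the two-stage removal-perturbation protocol.
Generation times are gamma(k, θ); the default calibration `θ = 2^(1/k) − 1`
makes the Euler–Lotka growth rate `Λ = (2^(1/k) − 1)/θ` equal 1 per hour for
every shape, so different noise levels (k = 1, 2, 5) are compared at equal
mean growth. A perturbation of strength ε removes each newborn daughter
independently with probability `1 − 2^(−ε)`, damping lineage fitness from
`d·ln2` to `(1−ε)·d·ln2`.

- **Pre-run.** Single newborn cells grow (with removal active) until every
  surviving lineage passes `T_max` (default 8 h); the residual time from
  `T_max` to each lineage's next scheduled division is pooled. These
  residuals are the "first division times" of the main run, which therefore
  starts from the quasi-stationary age distribution rather than from
  newborns — without this the finite-window growth rate is biased away from
  the Euler–Lotka value. Extinct pre-run cycles contribute nothing; an
  empty pool is a warning at pre-run time and an error at main-run time.
- **Main run.** Each of `n_main` progenitors founds one cycle; surviving
  lineage division counts at `T_max` give
  `Λ(ε) = (1/T_max) ln(N/n_main)`, and the ε = 0 run supplies
  `⟨h̃⟩_cl, ⟨h̃⟩_rs, S_KL2[D]` for the theory lines. At ε = 0 every cycle is
  a complete tree, so `to_ensemble` exports tree-mode data whose
  conservation law holds exactly; exporting survivors of ε > 0 as a
  chronological sample is allowed but flagged approximate (removal
  survivors are not a chronological draw).
- **Mother-daughter correlations.** With correlation r the daughter's
  generation time is gamma with shape `(r·τ_m/θ + k(1−r))/(1−r²)` and scale
  `(1−r²)θ`. This conditional kernel keeps the stationary mean kθ and
  variance kθ² exactly and has lag-1 autocorrelation r (shown analytically
  from the conditional mean `r·τ_m + kθ(1−r)` and conditional variance, and
  verified by simulation in the tests). The marginal stationary law is
  gamma(k, θ) to good approximation, not exactly.
- **Randomness.** One counter-based Philox stream per simulation call,
  seeded from the configuration; pre-run cycles and main-run progenitors
  are batched into a single vectorized generation loop, so identical
  (config, seed) pairs reproduce division-count multisets bit for bit.
- **Measured response slope.** The exact response
  `ΔΛ/Λ = −(1 + S_KL2/τΛ)ε + O(ε²)` is curved: over ε ∈ [0, 0.2] the
  quadratic term shifts a straight-line regression slope by an amount that
  exceeds Monte-Carlo error at k = 1. `fit_response_slope` therefore fits
  `aε + bε²` and reports the linear coefficient as the measured initial
  slope.

## What the synthetic data emulate — and what they do not

The fixture generator covers the regimes the estimators must distinguish:
the exactly solvable micro-tree (D = 1, 2, 2), zero-heterogeneity trees
(all strengths 0), a strongly right-skewed "regrowth from dormancy" lineage
list (90% non-dividers, where S_KL2 > S_KL1 and W_n converges only at high
order), and gamma branching-process colonies. Random fuzz trees are built
by splitting random leaves, so the conservation law holds by construction,
and synthetic traits are noisy monotone functions of D so that trait and
fitness genuinely correlate.

What passing tests therefore demonstrate: the estimators recover the exact
identities and known values on data whose generating process satisfies the
framework's assumptions. What they do not demonstrate: robustness to
segmentation/tracking errors, non-binary or asymmetric division, lineage
loss, measurement noise in traits beyond simple additive Gaussian, or
environmental structure around cells — none of which the synthetic
generator produces.

## Uncertainty estimation

`resample` implements the two lineage-bootstrap schemes: *colony* (tree
data) draws Nτ lineages with replacement under the retrospective weights
and re-estimates `N̂0 = Σ 2^(−D)` per replicate (fractional N̂0 is accepted,
and the conservation law holds by construction); *chronological* (isolated
lineages) draws N0 lineages uniformly and re-estimates `N̂τ = Σ 2^D`.
Intervals are replicate mean ± 2 SD, with the default of 20 000 replicates
(tests use 200–2000). Replicates on which a statistic fails (e.g. a
degenerate resample) are dropped, with an error if more than 1% fail.

Known limitation: lineages of one colony share ancestry, and resampling
them as exchangeable units understates between-colony variability — the
±2 SD interval is calibrated for independent lineages (mother-machine
data), which is what the coverage test exercises; tree-topology-aware
bootstraps are out of scope.

## Problem sizes used in validation

The validation suite runs the removal experiment at 200 pre-run cycles and
200 main-run progenitors per sweep, 6 replicate sweeps per shape,
ε ∈ {0, 0.05, 0.1, 0.15, 0.2}. The strongly correlated response check
(r = 0.6) runs at `T_max = 6` with 60 progenitors × 4 replicates: the
correlation raises Λ to ≈ 1.6, so each progenitor founds ~3.5×10⁵ lineages
at `T_max = 8`, and the response law is an identity in `Q_cl(D)` that does
not depend on the window length. Kernel stationary moments are checked on
chains of 10⁵ generations against 3-SE bands (with the usual
`(1+r)/(1−r)` autocorrelation inflation of the naive standard errors).
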
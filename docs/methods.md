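# Methods

## The monitoring problem

Post-surgery survival is a continuous quality signal contaminated by
patient mix. Both charts in this package remove the predictable part of
log survival with a Phase-I regression on the Parsonnet score and monitor
the standardized residual stream with a lower-one-sided EWMA. The two
charts differ only in the regression producing the residuals:

* **RAEWMA** — censored log-linear AFT model, residual
  `e_t = (log T_t − x_tᵀβ̂)/σ̂`;
* **SVM-EWMA** — ε-insensitive support-vector regression of `log T` on the
  score, residual `r_t = log T_t − f̂(P_t)` standardized by the Phase-I
  pool mean and sample SD (n−1 denominator). Phase-II streams reuse the
  Phase-I constants.

## Models and estimation

**AFT fit.** `log T = β₀ + β₁P + σε` with ε standard normal by default
(logistic and Gumbel-minimum are selectable, giving log-logistic and
Weibull AFT laws). Censored records contribute `log S(z)` survivor terms,
so 30-day censoring does not bias the estimates. The optimizer is BFGS on
`(β, log σ)` started from OLS on the uncensored records — deterministic
given the data. For uncensored cohorts with normal errors the MLE is the
OLS/n-denominator closed form and is used directly. Censored records are
excluded from the residual *pool* by default (their residual is not
observed); an `impute_conditional` policy replaces them by
`E[ε | ε > c_t]` under the fitted error law.

**SVM core.** The hard-margin classification dual and the ε-SVR dual are
both instances of `min ½λᵀQλ + pᵀλ` with one equality constraint and box
bounds, and are solved by one SMO-type solver (maximal-violating-pair
selection with a second-order choice of the partner index, incrementally
maintained gradient, and an analytically clipped two-variable step). Only
the n×n base kernel matrix is stored, so the 2n-variable SVR dual needs no
4n² workspace. Stopping rule: KKT gap ≤ `tol` (default 1e-4; tests use
1e-9 ... 1e-12 when comparing against a reference QP solution).
Non-separable hard-margin input is rejected up front by an exact LP
feasibility check of `y_i(⟨w,x_i⟩+b) ≥ 1`, which is cleaner than waiting
for the dual to diverge (divergence is only linear in the iteration
count). The hyperplane offset uses the two largest-multiplier support
vectors, one from each class (`b* = −½⟨ω*, x_r + x_s⟩`), a deterministic
tie-break; SVR recovers its bias from free (strictly inside-the-box)
multipliers, or the midpoint of the KKT-feasible interval when none is
free.

Default SVR hyperparameters: rbf kernel with the median-pairwise-distance
bandwidth (γ = 1/(2h²), deterministic strided subsample of ≤1024 points),
C = 1, ε = 0.1. These are configuration, not fidelity claims: published
run-length tables depend on the analysts' SVR settings, which are not
fully specified, so all three are exposed and logged in the CLI manifest.
Note that an exact ε-SVR minimum-norm fit may tilt a realizable linear
trend within its tube; extrapolation error can reach a multiple of ε even
when all training residuals are inside the tube.

## The chart

`F_t = min{λv_t + (1−λ)F_{t−1}, ξ}` with `F_0 = ξ`, ξ the Phase-I residual
mean (≈ 0 after standardization). Signal rule: `F_t < LCL_t` with the
time-varying limit of the exact t-step EWMA SD (an `asymptotic` mode
freezes the limit at its t→∞ value). A printed rule of the form
"|F_t| < L" cannot be meant literally for a lower-one-sided chart — it
would flag in-control processes — so the limit-crossing rule above is
used; this interpretation is the same one implied by the chart's
"detect decreases in survival" design. With λ = 1 and the clip disabled
the chart reduces exactly to a one-sided Shewhart rule, which is the
closed-form oracle used throughout the tests
(`ARL = 1/Φ(δ − L)`).

## Run-length engine

Streams are i.i.d. bootstrap draws from the Phase-I residual pool (or a
parametric standard normal for oracle work). Shift magnitudes δ ≥ 0 are
applied in the *signaling* direction, `v_t − δ`, zero-state (from t = 1).
Percentiles use linear interpolation between order statistics, hence
fractional values. Runs reaching the horizon (default 10⁶, must be < 2²¹)
are counted at the horizon and reported in `censored_runs`.

**Common random numbers.** Calibration bisects on L and needs ARL(L) to be
monotone across evaluations. Draws are therefore generated by a
counter-based SplitMix64-style mixer addressed by (replication, step) and
keyed by the evaluation seed: each replication sees the same stream for
every candidate L, so each replication's run length — and hence the
estimated ARL — is non-decreasing in L, and every estimate is
bit-reproducible for a seed. A scalar path (`simulate_run_length` +
`run_chart`) exists alongside the vectorized engine and the two are tested
to agree run-for-run on identical streams.

**Calibration.** Bracket grown multiplicatively from the low end, then
bisection; evaluations truncate runs at 25× the target ARL (truncation
probability ≈ e⁻²⁵ near the optimum) so overshooting candidates stay
cheap. Tolerance `max(1, 0.5% of target)`; because the CRN ARL(L) curve is
a step function at finite reps, the step nearest the target can exceed the
tolerance, in which case the best L found is returned together with the
achieved ARL̂₀ and its standard error.

## Synthetic cohorts

The generator emulates the structure the models assume: Parsonnet scores
from a truncated-geometric pmf on 0..100 (right-skewed, mass near zero;
default mean 10, configurable, with point-mass and explicit-pmf options),
log survival linear in the score with the published Phase-I coefficients
(β₀ = 5.07026, β₁ = −0.03348, σ = 0.57), i.i.d. errors, optional surgeon
group offsets on the log scale (off by default), and right censoring at 30
days. Latent uncensored times are retained in the records purely for
oracle checks; no fitting path reads them.

What it does **not** emulate: the empirical Parsonnet histogram of any
real registry, serial correlation or case-mix drift, informative
censoring, and surgeon learning effects. Passing tests therefore
demonstrate the correctness of the machinery and the internal consistency
of the published in-control surface — not out-of-control ARL magnitudes on
real data, which depend on the registry's residual distribution.

## Problem sizes and numerical choices

Phase-I pools use 5,000 uncensored records; calibration and profile
estimates use 50,000 replications in `scripts/acceptance.py` and 20,000 in
the test suite, with Monte-Carlo tolerances scaled accordingly (3 combined
standard errors). Degenerate inputs raise typed errors: all-censored
cohorts, zero-variance residual pools (perfect interpolation), empty
streams, non-separable hard-margin data, sub-floor (< 30) calibration
pools, λ outside (0,1]. Exact survival to the censoring horizon counts as
observed, not censored.

## Known limitations

* Hard-margin classification is linear-kernel only (the classical dual in
  feature space); kernels are available on the SVR side.
* ARL estimation is Monte-Carlo only; no Markov-chain or
  integral-equation approximations, and no steady-state (delayed-shift)
  ARL.
* The SRM-style bound "no data point nearer than 1/max‖x‖ to the
  hyperplane" is a hypothesis-class assumption, not a property of every
  max-margin solution; it is exposed as a diagnostic and verified only on
  geometry that satisfies it.
* `calibrate_L` assumes ARL(L) is increasing over the search bracket,
  which holds for any pool with downward mass but is unverified for
  pathological pools (e.g., strictly positive residuals).
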
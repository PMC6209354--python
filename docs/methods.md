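# Methods

## Fish dynamics: periodic VAR in state space

The latent abundance index of one species in bay `j` at half-year time `t`
follows

    x_{t,j} = b_{1,s} x_{t-1/2,j} + b_{2,s} x_{t-1,j}
              + w_{1,s} ε_{t,j-2} + w_{2,s} ε_{t,j-1} + w_{3,s} ε_{t,j}
              + w_{4,s} ε_{t,j+1} + w_{5,s} ε_{t,j+2},
    y_{t,j} = x_{t,j} + v_s e_{t,j},

with `s ∈ {spring, fall}` chosen by the season of the target time, and ε, e
i.i.d. standard normal. The shared shocks ε couple each bay to its two
neighbours on either side in coastal order (GL, MG, SA, AR, CC, UL, LL);
loadings that would refer to bays beyond the coast ends are structurally
zero, so the process-noise loading matrix `W_s` is banded with bandwidth 2.
The model is periodic (two seasons of parameters), second order (two
half-year lags), and observed with seasonal measurement error.

Assumptions worth stating plainly: dynamics are linear and Gaussian on the
log/z-score scale; the spatial coupling acts through correlated process
noise, not through transition terms; there is no feedback from fishing effort
to fish mortality; and only the stationary fluctuation around the long-run
trend is modelled (polynomial trends are removed and never extrapolated).

### Identifiability and constraints

`W_s` enters the likelihood only through `W_s W_sᵀ`, so the signs of the `w`
loadings are not identified. All `w` are constrained non-negative and `v_s`
strictly positive, which makes reported coefficients unique and matches the
sign of every published estimate for this system. Autoregressive `b`
coefficients are unconstrained.

### Candidate set and selection

The full model has 16 coefficients. The two observation scales (`v1`, `v2`)
and the two `w4` loadings are always included; candidates are all proper
subsets of the remaining 12 (at least one excluded), which gives exactly
2¹² − 1 = 4095 specifications. BIC uses `n` = number of scalar observations
(490 for a 70×7 panel); ties break toward fewer parameters, then the
lexicographically smaller mask. Models for which no start converges, or
whose observed information is singular at the optimum, are treated as not
estimable and dropped before selection.

### Likelihood, initialization, optimization

The exact Gaussian likelihood is computed by a Kalman filter over the
stacked state `[x_t; x_{t-1/2}]` (dimension 14). The initial state is the
stationary distribution of the annual composite map (spring∘fall), obtained
from the discrete Lyapunov equation; a diffuse prior (variance 10⁷) is
available for non-stationary candidates, and the stationary path raises an
error suggesting it when the composite spectral radius reaches 1. Missing
cells are skipped in the update step.

Because the periodic Riccati recursion converges geometrically, the filter
freezes the per-season gain and innovation covariance once the per-phase
prior covariance repeats to 10⁻¹¹ (fully observed rows only); thereafter each
step costs one matrix–vector product. The frozen path is exact to well below
test tolerances and is verified against the unfrozen filter and against a
brute-force joint-Gaussian density on small panels.

Fitting maximizes the likelihood with L-BFGS-B under the sign constraints,
from `n_starts` randomized initial points (`b ~ U(−0.5, 0.5)`,
`w, v ~ U(0.1, 1)`; 5 starts by default). Standard errors come from the
finite-difference Hessian of the negative log-likelihood at the optimum.
Simulation draws the initial stacked state from the stationary covariance,
iterates a 20-year burn-in (fall/spring pairs, preserving phase), and emits
observations; it is deterministic given the seed.

## De-trending and standardization

Each of the 28 series (2 species × 7 bays × 2 seasons) is handled
separately. A polynomial in the year index 1..n of order 0–3 is selected by
leave-one-out cross-validation (computed with the OLS hat-matrix identity,
verified against a literal refit-each-fold loop); ties go to the smaller
order. Order 0 is included so untrended series are left alone. The
de-trended series is residual + series mean, which preserves the mean
exactly. Stationarity is screened with the ADF test (constant, no trend —
the series are already de-trended — lags 0–3 by AIC, α = 0.1).

The spring/fall series are interleaved into a 70×7 panel, floored at
10⁻³ × column mean (residual + mean can dip to or below zero; the floor
keeps the log transform defined and the round trip invertible on the floored
domain), logged, and z-scored per bay column. The floor, log means and log
sds are stored so simulated panels can be mapped back to the CPUE scale by
`exp(z·sd + mean)`.

## Angler demand

Site choice is a conditional logit in one-way distance and expected catch of
the two species, with no site-specific constants. All exponentiations go
through max-shifted log-sum-exp. Because the choice coefficients were
estimated on anglers outside Texas, the model is calibrated to Texas by
solving the share-matching system: with `D_j = exp(β_d d_j)` and
`C_j = exp(β_cR c_jR + β_cS c_jS)`,
`D_j = (T_j/T_1)(C_1/C_j) D_1`, anchored at `d_1 = 100` miles. Catch rates
`c̄_j` are base-season harvest divided by trips. The calibration is exact:
plugging the solved distances back into the logit reproduces the observed
trip shares to 10⁻¹⁰ (a property test over random positive tables).

Participation is logistic in the inclusive value with dissimilarity
coefficient `λ = −(β_d / cost-per-mile)·WTP`, WTP $30 per trip. The $0.5,
$1 and $2 per-mile scenarios give λ = 4.92, 2.46 and 1.23 by this formula
(we use the formula value 4.92 at $0.5 throughout; a published figure quotes
4.96 for that scenario, which the formula does not yield). Base
participation spreads 20 fishing days per year over a 189-day high and
176-day low season proportionally to base trip totals; the day-weighted
average recovers 20/365 exactly. Changes in participation use the
first-order update `ΔP_T = λ(1−P_T)P_T·ΔIV` by default (clamped to [0,1],
clamp events logged); an exact-logistic mode recovers the implied intercept
`α = logit(P_T) − λ·IV` and is available for robustness checks. The
intercept itself is never estimated — the model carries base `P_T` directly.

The elasticity of trips to bay `j` with respect to its catch of one species
decomposes as

    ε_jT = λ(1−P_T)β_c P_j c_j  +  β_c c_j (1−P_j),

participation plus site choice. Both components are verified against a
central finite-difference derivative of `ln(P_T·P_j)` computed through the
choice probabilities and the exact logistic. Evaluated at base rates and
base shares these elasticities are internally consistent but do not
reproduce one published elasticity table for this system, whose input scale
we could not reconstruct; the identity-based checks above are the ground
truth for this implementation.

### Expected-catch smoothing

An optional smoother forms the expectation at a site as base rate plus a
weighted mean of catch anomalies: the current own-site observation has
weight 1, other sites are discounted geometrically per mile
(`(1−rate)^miles`; 1%/mile red drum, 8%/mile spotted seatrout), the previous
two-month wave by 0.54/0.35, and the same wave one year back by ~0/0.84.
The published description does not pin down how the three weights compose;
we multiply them per observation and normalize. With no inter-bay distance
matrix supplied (the Texas simulation provides none) the smoother reduces to
each site's own history and is off by default in the coupled runs.

## Coupling

Spring CPUE informs the following high season, fall CPUE the low season of
the same year. Simulated gillnet CPUE is anchored to recreational
harvest-per-trip by proportional scaling — each bay/season series is scaled
so its long-run mean equals the base rate, making the coupling invariant to
the units of the simulated index. The per-season number of trip occasions is
backed out as `N = ΣT_j / P_T(base)`, so holding catch at its long-run mean
reproduces the base trip table exactly (the calibration fixed point, tested
to 10⁻⁶ relative). Species panels are simulated independently. Across the
three travel-cost scenarios the standard deviation of total trips decreases
as cost per mile rises — cheap travel lets anglers chase conditions — and
this ordering is checked over 20 seeds.

## Synthetic data

The generators mirror the study's shape: 35 years × 2 seasons × 7 bays.
Trended CPUE panels are `exp(quadratic log-trend + 0.35 × stationary VAR
component)` per bay, with trend slopes/curvatures drawn once per bay from
small normals (sd 0.012/yr and 0.0006/yr²) around a log-level of −1.5
(≈0.22 fish per net-hour, a typical gillnet magnitude); the stationary
component uses sparse study-scale parameters (one-year-lag autoregression
0.2–0.4, own/neighbour noise loadings 0.2–0.75, observation scales
0.3–0.7). Choice records jitter site distances ±30% and catches log-normally
(σ = 0.3) per trip before sampling the chosen site from the logit, giving
the across-trip covariate variation real intercept surveys have. Every
generator call splits its seed into named substreams so adding a component
does not shift the others.

What the synthetic data do not emulate: survey design (waves, strata,
intercept weights), zero-inflation and discreteness of real catch counts,
non-Gaussian tails, and any effort-to-mortality feedback. Passing tests on
synthetic data therefore demonstrate correctness of the algorithms under the
model's own assumptions, not goodness of fit to Texas monitoring data.

## Problem sizes used in the test suite

Estimator-recovery checks use simulated panels of 2000 half-year steps
(recovered coefficients within 3 standard errors of truth); the
likelihood-exactness property uses 200 random small systems (≤5 steps, ≤3
bays) against a brute-force joint Gaussian; BIC selection consistency uses
5 replicates of 500-step panels against perturbed candidate sets; scenario
variance ordering averages 20 seeds of 35-year runs. The full 4095-model
sweep is supported (`--sweep full`) but the test suite and examples exercise
reduced sweeps — the candidate enumeration itself is verified exhaustively.

## Known limitations

- The mandatory process-noise loadings are the `w4` (j+1 neighbour) terms,
  not the own-bay `w3`, mirroring the published model statement; a candidate
  with all optional terms excluded therefore has no own-bay process noise.
- The linearized participation update can leave [0,1] for large inclusive-
  value swings; it is clamped and counted rather than hidden.
- Calibrated distances are a device to match shares; they are not
  geographic distances, and conclusions should be read at the level of
  qualitative response, not point prediction.
- The conditional-logit estimator is exercised on synthetic records only;
  fitting to real intercept surveys (and estimating the smoothing weights)
  is out of scope.
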
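# Methods

This note records the models, estimators, numerical choices and known
limitations behind `genestab`, in the package's own words.

## Deterministic model

Two strains compete in batch culture: the engineered strain E (carrying a
costly, mutationally fragile transgene) and the revertant strain R
(transgene lost, wild-type fitness). Both grow logistically with a shared
density factor (1 − N/K); the engineered strain's per-capita birth rate is
reduced by the selection coefficient s, and each engineered birth yields a
revertant offspring with probability µ (loss acts at replication; living
cells are never converted, and back mutation is ignored — regaining a lost
transgene function is vastly less likely than losing it):

    dN_E/dt = r(1−s) N_E (1 − N/K)(1−µ)
    dN_R/dt = r N_R (1 − N/K) + r(1−s) N_E (1 − N/K) µ.

During exponential phase (N ≪ K) the frequency p = N_E/N decouples from
density and follows dp/dt = −r p [µ + s(1−p−µ)], whose exact solution, with
a = s(1−µ) + µ, is

    p(t) = p₀ a e^(−rat) / (a − s p₀ (1 − e^(−rat))).

Assumptions worth keeping in mind: a single revertant class (one dominant
loss pathway), constant exponential growth between transfers, selection
expressed through growth rate only (no death/clearance), and deterministic
frequency dynamics (valid at large population sizes).

### Parameters

| symbol | meaning | units | typical default |
|---|---|---|---|
| r | wild-type per-capita growth rate | h⁻¹ | 0.1 (0.2878 for 1000× daily dilution) |
| s | selection coefficient against the transgene | – | 0–0.2 |
| µ | loss probability per replication | – | 10⁻⁵–10⁻¹ |
| K | carrying capacity | cells | 2×10⁶ |
| T | transfer interval | h | 24 |
| β | bottleneck size at transfer | cells | 10⁴ |
| n | genotyped sample per transfer | cells | 100 |
| R | replicate lineages | – | 3 |

### Half-life

The time from a pure culture until half the population has lost transgene
function is t₅₀ = ln[µ(1−s)/(µ(1−s)+s(1−µ)+µ)]/(−r[s(1−µ)+µ]) (natural
log; the neutral special case collapses to ln2/(rµ), i.e. the "0.7/(rµ)"
rule of thumb). `half_life_gain` compares t₅₀ before and after cutting µ
and/or s by factors k_µ, k_s ≥ 1; the tidy grid form (default 50×50,
log-spaced factors 1–100 per axis, configurable) supports contour plots
that show at a glance whether re-engineering effort should target mutation
or selection. Degenerate conventions: s = µ = 0 is an error for t₅₀
(nothing is ever lost) but p(t) returns p₀ as the continuous limit of the
0/0 form; p₀ ≤ ½ returns t₅₀ = 0 rather than an error so that grid code
never crashes; µ = 0 from a pure culture gives t₅₀ = ∞.

## Stochastic simulator

The simulator realizes the three birth reactions implied by the ODE —
engineered birth (propensity r(1−s)N_E f (1−µ), with f = max(0, 1−N/K)),
engineered parent → revertant offspring (same propensity × µ/(1−µ) ratio,
implemented as the complementary Poisson channel), and revertant birth
(r N_R f) — between transfers, then a hypergeometric bottleneck of β
founders and a hypergeometric genotyped subsample of n drawn *from the
founders*. The t₀ sample is drawn from the founding culture itself, so a
pure start yields x₀ = n deterministically. One master seed spawns
independent per-replicate streams (`numpy` `SeedSequence`), making output
bit-reproducible.

Numerics: adaptive **midpoint tau-leaping** — the step is bounded so that
every propensity changes by ≲ 5% per leap (dt = ε/[A(1/N + 1/(K−N))],
ε = 0.05), and Poisson event counts are drawn from propensities re-evaluated
at the deterministic half-step state. The midpoint evaluation matters:
freezing propensities across a leap (plain first-order leaping) slows
effective evolutionary time by ~ε/2 and biases the mean frequency
trajectory upward by ~10⁻³ per cycle — an order of magnitude beyond the
Monte-Carlo error of a 200-seed mean — which propagates into a visible
downward bias of recovered (µ̂, ŝ). Below 1000 individuals the simulator
falls back to the exact SSA. Population may overshoot K by at most one
leap's worth; the clamped density factor then stops growth (individuals are
never deleted).

## Continuous-time estimator

Each observation is x_j ~ Binomial(n_j, p(t_j)) with p(t) the closed form
above; replicates are independent and share (µ, s, r, p₀), so their
negative log-likelihoods add. Binomial coefficients are computed via
log-gamma (safe at n = 10⁶); p is clipped to [1e−300, 1−1e−16] inside the
likelihood only, so underflowed trajectories yield large finite penalties
rather than NaNs.

- **p₀ policy.** Default `pooled`: p₀ is fixed at the pooled t₀ sample
  frequency across replicates (the t₀ term is then parameter-free but
  retained). Alternatives: `fixed` (user value, e.g. 1) and `free`
  (estimated as a third parameter). Pooling mirrors standard practice and
  exposes the initial-impurity sensitivity: an undetected revertant
  fraction at t₀ mostly biases ŝ downward, which is why genotyping many
  individuals *early* is the efficient design.
- **Optimization.** Nelder-Mead in sigmoid-warped coordinates that map ℝ²
  onto µ ∈ [10⁻⁹, 0.5] (log₁₀ scale) and s ∈ [0, 0.95], started from the
  best points of a 5×5 log-spaced coarse grid (µ: 10⁻⁷–10⁻¹, s:
  0.005–0.5); NLL tolerance 10⁻¹⁰. Estimates within ~0.1% of a bound are
  flagged; all-x = n data pins µ̂ at its lower bound and flags s as
  unidentifiable (when µ = 0 and p₀ = 1, p(t) = 1 for *every* s).
  On noise-free n = 10⁶ data the optimizer recovers truth to < 1%.
- **Assumed r.** r is *not* estimated. Assuming r above its true value
  biases both µ̂ and ŝ downward; below, upward. The product r·a is what the
  data constrain tightly.
- **Confidence intervals.** Profile likelihood at the χ²₁ 95% cutoff
  (ΔNLL = 1.92), bisection in the warped coordinate, endpoints clipped at
  the parameter bounds and flagged. *Caveat*: these intervals quantify
  genotyping (binomial) noise only. Simulated experiments at default
  designs show empirical coverage near 60%, not 95%, because
  dataset-to-dataset variation is dominated by unmodelled process noise —
  Poisson variation in when early mutant lineages establish, and drift at
  the β = 10⁴ bottlenecks — plus the small downward bias of ŝ that the
  recovery regressions (slopes < 1) also reflect. Treat the intervals as
  optimistic lower bounds on uncertainty; replicate-level resampling or an
  explicitly stochastic likelihood would be needed for calibrated
  intervals.
- **Model-fit envelope.** Assuming the estimates are true, the sampled
  frequency at t_j has the equal-tail 95% Binomial(n_j, p̂(t_j))/n_j
  interval; data falling outside this envelope flag model violations
  (e.g. multiple mutational pathways). Discrete binomial quantiles make the
  envelope slightly conservative (~96–97% pointwise).

## Per-transfer (discrete) estimator

When within-culture growth is unknown or non-exponential but consistent
across cultures, the per-cycle recursion
p′ = p(1−S)(1−U)/[p(1−S) + (1−p)] replaces the continuous trajectory; the
likelihood machinery is identical, with the cycle index t/T in place of
time, and equal transfer spacing is required (violations are reported with
the offending rows). This recursion is the standard discrete
mutation–selection form, chosen here because it reproduces the continuous
model over one cycle to O(parameter²) under U = 1−e^(−rTµ), S = 1−e^(−rTs)
(verified to ~5×10⁻⁷ at µ = 10⁻⁴, s = 0.01, rT = 2.4; a *linear* S = rTs
mapping misses by ~6×10⁻⁵). Per-cycle estimates (U, S) and the cycle-count
half-life must not be numerically compared with per-hour (µ, s, t₅₀),
though the *relative* importance of mutation versus selection should agree
between engines; result records carry a note to that effect.

## Recovery (validation) study

For each of `count` datasets: draw s ~ Uniform(0.005, 0.2) and
µ ~ Gamma(shape 10, scale = mode/9) with mode 1.5^i × 10⁻⁵ growing
1.5-fold per dataset index i — spanning ~10⁻⁵ to beyond 10⁻¹ across a
50-dataset batch — truncated to µ ≤ 0.1 (the literal mode exceeds 1 past
i ≈ 29, which is not a probability; truncation is proper conditional
sampling via the inverse CDF, with the analytic x^(shape−1) tail form when
the cap is in the far tail, rather than a point mass at the cap). Simulate
the full stochastic experiment, fit with an assumed r, regress estimates on
truth with unweighted OLS on raw scales. Under 24-h transfers (cultures
stay ≪ K) slopes are near 1; under 72-h transfers each culture saturates
(from 10⁴ founders at r = 0.1, N(72 h) ≈ 0.87K by the logistic closed
form), evolution slows relative to the exponential clock the estimator
assumes, and both slopes drop to ~0.7–0.8. Impurity and truncation
scenarios are expressed through the design (`initial_revertants`,
`truncation_freq`; truncation stops a replicate once the *sampled*
frequency reaches the threshold, retaining the triggering sample).

### What the simulator does and does not emulate

Simulated data include demographic stochasticity, bottleneck drift,
genotyping subsampling and density-dependent saturation — the features that
drive the validation results. They do not include: death or clearance,
multiple revertant classes with distinct (µ, s), phenotypic lag between
loss and expression change, measurement misclassification, or varying r
across cultures. A green recovery test therefore establishes correctness of
the estimator *under its own generative assumptions* (plus saturation
stress), not robustness to those unmodelled features.

## Numerical conventions

- Times are hours (real-valued); replicate labels are opaque strings;
  frequencies dimensionless.
- The closed-form p(t) is evaluated from a single exponential term arranged
  to avoid cancellation; at extreme times it underflows to exactly 0
  (never negative), except the µ = 0, p₀ = 1 branch which is exactly 1.
- The deterministic integrator (LSODA, rtol 10⁻¹⁰) does not clamp the
  logistic factor, so populations above K relax back; clamping exists only
  in the stochastic propensities.
- OLS summaries report both conventional and robust-SE-compatible inputs
  (rows are returned, so any regression can be recomputed).
- All randomness flows from explicit `numpy` Generators or integer master
  seeds; no global RNG state is touched.

## Known limitations

- Single-mutation model: a second, phenotypically distinct loss pathway
  biases estimates; inspect the fit envelope.
- r must come from outside the data; errors in r propagate directionally
  into (µ̂, ŝ).
- Profile CIs undercover on realistic stochastic data (see above).
- The discrete-model recursion is a principled reconstruction; treat
  cross-tool comparisons of per-cycle estimates with care.
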
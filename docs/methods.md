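# Methods

## Model

Both groups are modelled as normal with a common error variance,
`Y1i ~ N(μ1, σ²)`, `Y2j ~ N(μ2, σ²)`, and inference targets the
standardized effect size `δ = (μ1 − μ2)/σ`.  With Jeffreys' reference
prior `p(σ²) ∝ 1/σ²` on the variance and any proper prior `π(δ)` on the
effect size, the two-sample likelihood reduces to the noncentral-t form:
the pooled t-statistic is distributed as `T_ν(t | √n_δ · δ)` with
`ν = n1 + n2 − 2` and `n_δ = n1 n2/(n1 + n2)`, so every marginal
likelihood is a one-dimensional integral

    m(π) = ∫ T_ν(t | √n_δ δ) π(δ) dδ

and the posterior of δ is proportional to the integrand.  All priors on
δ are Cauchy `C(μ_δ, γ)`; the t_ν0 effect-size prior of the
non-overlapping model is supported for ν0 = 1, where it *is* the Cauchy
(other ν0 raise `NotImplementedError`; the general t-to-Cauchy reduction
is deliberately out of scope).

### Which t-statistic

The statistic fed to every Bayes factor and posterior is the **pooled
(Student) t** with df = n1 + n2 − 2.  The marginal-likelihood identity
above is derived under a common σ, so the pooled statistic is the
internally consistent choice even when the data-generating settings have
unequal group SDs; Welch's statistic (with Welch–Satterthwaite df) is
used only for the frequentist TOST and descriptive output.  This is a
genuine modelling choice, documented here because the simulated settings
are heteroscedastic: the common-σ Bayes machinery is then an
approximation, applied identically across all methods so comparisons
between them remain fair.

### The four Bayes factors

* JZS: `BF01 = T_ν(t) / m(C(0, γ))` — point null vs Cauchy alternative.
* OH: null `C(0, r0)` vs alternative `C(0, r1)`; by transitivity of
  Bayes factors `BF01 = m(C(0, r0)) / m(C(0, r1))`.  Default
  `r0 = r1/10`.
* NOH: prior split at the region (l, u);
  `BF01 = [∫_l^u T π / ∫_l^u π] / [∫_{(l,u)^c} T π / ∫_{(l,u)^c} π]`.
* hybrid: numerator `π0 · T_ν(t) + (1 − π0) · m0` over the NOH
  alternative marginal, with m0 the NOH null marginal.  Implemented but
  excluded from the default simulation grid: π0, the prior probability
  of an *exact* zero effect, has no defensible default in biomedical
  applications.

A documented convention note: the interval Bayes factor is consistent in
the direction BF01 → ∞ when the true δ lies inside the region and
BF01 → 0 when it lies outside (unless δ sits exactly on a boundary).
Prose occasionally states this with the subscripts swapped; the test
suite asserts the convention-consistent direction.

## Numerics

Marginals are computed by adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, abs. tol. 1e-10, rel. tol. 1e-8) with the real
line split at the region boundaries, the likelihood peak
`δ̂ = t/√n_δ` ± 5 likelihood SDs, and the prior location ± 5 prior
scales.  Both factors of the integrand can be narrow spikes (large n, or
a nearly degenerate prior scale), and unsplit quadrature misses them.
The summed per-panel error estimates are propagated through every ratio
into `BFResult.numerical_error`; a panel sum that fails its tolerance by
a wide margin raises `NumericalError`.  Ratios are formed in log space
with a 1e-300 floor so that a marginal underflowing to zero saturates
the log Bayes factor instead of producing infinities.  The noncentral-t
density itself is wrapped to clamp the NaN/overflow failures that the
backend exhibits deep in the tail at large df (the true density has
underflowed there, so 0 is the correct value).

## Posterior and interval estimates

The posterior of δ is one-dimensional, so it is represented on a dense
deterministic grid rather than by MCMC: a coarse 2001-point pass locates
the posterior mean and SD, and the final grid (default 4001 points)
spans the wider of mean ± 12 SD and δ̂ ± 8 SD, covering essentially all
mass for the t-like tails involved.  Inverse-CDF sampling on the grid
reproduces draw-based workflows exactly and reproducibly.

* **95% HPD**: shortest interval with ≥ 95% mass, by bisection on a
  density threshold (the posterior is unimodal by construction); ties at
  flat density resolve toward the shorter interval.  Achieved mass is
  within ±0.001 of the target on the default grid.
* **Full interval** (the "100% ROPE"): the central interval of mass
  1 − ε with ε = 1e-6.  A literal 100% interval of a Cauchy-prior
  posterior is the whole real line, which would make the full-ROPE test
  vacuous; the 1 − 1e-6 central region is the deterministic counterpart
  of the min/max of a few thousand posterior draws.  Both ε and a
  min/max-of-draws mode are configurable.
* **Support interval**: `{δ : p(δ|t)/p(δ) > k}`, default k = 1 — the
  values the data corroborated.  The ratio is unimodal here, so the set
  is an interval; it can be empty, which downstream maps to
  *inconclusive* (an empty set would vacuously lie inside any region,
  and treating that as acceptance would be absurd).

Grid-versus-draws fidelity: implementations that estimate these
intervals from a few thousand MCMC draws via kernel/logspline density
estimates produce slightly *narrower* support and full intervals
(under-sampled tails).  The practical consequence observed in the
simulations is a support-interval ROPE test a few power points below
draw-based reports at large n, while the HPD results agree closely.

## Decision rules

BF tests: `accept_H0` iff BF01 ≥ 3, `reject_H0` iff BF01 ≤ 1/3
(at least moderate evidence either way); boundary values count as
decisive, fixed for determinism.  ROPE tests: acceptance requires the
interval to lie inside the region with *closed* comparisons (an endpoint
exactly on the boundary is inside — the worked acceptance example has an
HPD endpoint flush with the region boundary); rejection requires strict
separation; anything else is inconclusive.  Classification against the
simulation truth: reject under a true null is a type I error; accept
under a present effect is a type II error; reject under a present effect
counts toward power; inconclusive results enter no error rate.

## Simulation study

Four data-generating settings (group SDs are *standard deviations*, not
variances — forced by the standardized effect sizes the settings imply):

| label  | group 1           | group 2           | true δ  |
|--------|-------------------|-------------------|---------|
| null   | N(0, 1)           | N(0, 1)           | 0       |
| small  | N(2.89, 1.84)     | N(3.5, 1.56)      | −0.357  |
| medium | N(254.08, 2.36)   | N(255.84, 3.04)   | −0.646  |
| large  | N(15.01, 3.4)     | N(19.91, 5.8)     | −1.03   |

Defaults: per-group n from 10 to 200 in steps of 10; prior scales
{1/√2, 1, √2} (medium/wide/ultrawide); regions [−0.05, 0.05],
[−0.1, 0.1], [−0.15, 0.15]; 1000 replicates per cell.  The acceptance
script and test suite run reduced designs (300–500 replicates at the
sample sizes where behaviour is most distinctive) and always carry
binomial Monte-Carlo standard errors, so tolerance checks are
principled.  Replicate datasets are seeded by
`SeedSequence(master_seed, spawn_key=(setting, n, replicate))`, so every
method sees the same datasets within a (setting, n) block, results are
independent of cell evaluation order, and cells can be parallelized
without changing any number.  The synthetic generator emulates exactly
the idealized two-normal-groups world of the study design; it does not
emulate skewness, outliers, unequal group sizes or non-normal noise, so
passing error-rate checks demonstrate behaviour under the stated model,
not robustness to its violations.

## Region selection

`select_design` is a pure function of a results table and the criteria
(α_max, power_min, attainable n, prior scale, effect label).  The n is
floored to the largest simulated n not exceeding the request; the
admissible set is every (method, region) pair with estimated α ≤ α_max
under the null setting and estimated power ≥ power_min under the effect
setting; ranking is narrowest region first (a narrower region makes the
equivalence statement more precise), then lower α, then higher power.
Point estimates are compared by default; a conservative mode demands a
two-standard-error margin, which is advisable for reduced-replicate
tables.  The prior scale is a hard filter: ranking across prior widths
in one call is refused, because tuning the prior to reach an error
target inverts the logic of prior elicitation.

`select_by_total_error` bounds α + (1 − power): the non-detection rate
plays the role of the type II error, i.e. an inconclusive result counts
as a failure to detect.  This is the definition under which the
reported total error rates of the interval-BF tests (≈30% at n = 170
for the small effect) are reproduced; the stricter "accepted although an
effect exists" rate is still available per cell in the `type2` column.
The variant assumes equal losses for both error kinds, which is often
unrealistic in biomedical work — the choice of loss structure is the
user's.

## Known limitations

* Only two-sample designs on the standardized effect-size scale; the
  TOST operates on the raw mean difference, but no raw-scale posterior
  or ROPE is provided.
* Only Cauchy (t1) effect-size priors; no normal priors, no bridge
  sampling (unnecessary in one dimension).
* Equal group sizes in the simulation grid; for unequal real designs
  the smaller group size is the conservative entry point for selection.
* One-sided superiority/inferiority regions are expressible as
  half-open regions in principle but are not simulated or selected for.
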
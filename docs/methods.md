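# Methods

## Outcome models

All three analyses are Bayesian logistic regressions of 90-day all-cause
mortality on treatment allocation (T = 1 for the lower oxygenation target)
adjusted for the randomization strata: COPD, haematological malignancy, and
site. Site enters as a partially pooled varying intercept
`u_s ~ Normal(0, σ_site)` with `σ_site ~ half-Normal(0, 1)`: with ~35 sites
and ~80 patients per site, fixed site effects would be fragile, and partial
pooling is the standard compromise. When only one site is present the site
term is dropped (it would be confounded with the intercept).

Nuisance priors, all on the log-odds scale and overridable through
`ModelSpec.nuisance_scales`:

| parameter                      | prior                | rationale |
|--------------------------------|----------------------|-----------|
| intercept α                    | Normal(0, 2.5)       | weakly informative at centred covariates |
| binary adjustment coefficients | Normal(0, 1)         | same spirit as the weak treatment prior |
| continuous slope δ, interaction η | Normal(0, 1) per SD | variables standardized internally |
| σ_site                         | half-Normal(0, 1)    | plausible between-site spread |
| σ_a, σ_b (subgroup pooling)    | half-Normal(0, 0.5)  | subgroup deviations smaller than main effects |

The subgroup model pools both subgroup intercepts `a_g` and treatment-effect
deviations `b_g`. Whether the original analysis also pooled subgroup
intercepts is not documented; both terms are included here because subgroups
of a severity marker plainly differ in baseline risk, and `a_g` can be
disabled (`include_subgroup_intercepts=False`) or effectively un-pooled by
raising its prior scale. The two pooling scales are independent
configuration keys (`sigma_subgroup_intercept`, `sigma_subgroup_effect`) so
that the no-pooling and complete-pooling limits of the treatment effects can
be expressed without touching the intercepts.

Continuous variables in the interaction model are standardized internally
(sampler geometry); δ and η are rescaled to per-original-unit effects before
they are stored, and conditional-effect curves are evaluated on the raw
scale using the stored centring. The PaO2:FiO2 interaction model adds an
open-vs-closed oxygen-system adjustment (closed = reference), mirroring the
pre-specified analysis.

## Priors for the treatment effect

* weak: Normal(0, 1) on the log-OR — 95% prior mass on ORs 0.14–7.10.
* sceptic: Normal(0, σ_s). The protocol value of σ_s is not public; the
  default 0.355 places 95% of prior mass on ORs within [0.50, 2.01], the
  conventional sceptical calibration, and is exposed in configuration.
* evidence-based: a DerSimonian–Laird random-effects meta-analysis of earlier
  trials' 2×2 mortality tables gives pooled log-OR μ, its SE, and τ²; the
  prior is the *predictive* distribution Normal(μ, √(se² + τ²)) rather than
  the pooled-mean distribution Normal(μ, se), transferring between-study
  heterogeneity into prior width — the wider, more honest choice for a new
  trial's effect. Zero cells get the 0.5 continuity correction on all four
  cells (Woolf). The packaged three-study CSV is an *illustrative* fixture
  with synthetic arm counts of realistic magnitude; users transcribe real
  trial arms for a genuine evidence-based prior.

## Quintile subgrouping with ties

Five near-equal groups per variable such that patients sharing a value are
never split. Distinct values are treated as indivisible blocks; because the
number of groups is fixed, "nearest to equal size" (minimal summed squared
deviation from n/5) is equivalent to minimizing the sum of squared group
sizes, which a dynamic program over contiguous block runs solves exactly
(ties towards the earliest cuts, compared from the last cut backwards). The
test suite checks the DP against brute-force enumeration on all short tied
vectors. A percentile-breakpoint rule was considered and rejected: on tied
data it can leave groups empty and produce avoidably unequal sizes (e.g.
sizes {4,0,2,2,2} where {4,2,1,1,2} is achievable). New values at prediction
time fall to the group whose upper boundary is the first not below the value;
values outside the observed range go to the nearest boundary group with a
warning. Norepinephrine dose is zero-inflated: non-users (exact zeros) form
group 1 and the positive doses are split into four near-equal groups.

## Posterior standardization

Adjusted event probabilities fix every adjustment variable at its most common
level (ties to the reference level: 0, or the smallest site ID), applying
"most common value" literally to site as well — the modal site's posterior
intercept draws enter the linear predictor rather than zero. Per draw,
p₀ and p₁ are the inverse-logit of the two arms' linear predictors, and
RD = p₁ − p₀, RR = p₁/p₀, OR = odds₁/odds₀ hold exactly draw by draw.
Summaries are posterior medians with percentile 2.5/97.5 intervals.
Threshold probabilities are strict-inequality draw fractions, P(RR < c);
equality has measure zero for continuous posteriors and is counted with the
lower side (a degenerate point mass at exactly OR = 1 is reported separately
in interaction summaries). The default RR thresholds
{0.67, 0.80, 0.90, 1.00, 1.11, 1.25, 1.50} bracket the a-priori hypothesised
20% relative reduction (RR < 0.80); RD thresholds are {−5, −2, 0, +2, +5}
percentage points. The full protocol list is not public, so both sets are
configurable. Population-average (marginal) standardization is deliberately
not offered — the modal-profile convention is the analysis being emulated.

## Sampler

An adaptive No-U-Turn sampler (slice variant, max tree depth 10) written
against analytic log-posterior gradients; random-effect blocks use the
non-centered parameterization with scales sampled on the log scale (Jacobian
included). Warm-up adapts the step size by dual averaging (target acceptance
0.8) around a sequence of doubling windows that re-estimate a diagonal mass
matrix from warm-up draws; post-warm-up tuning is frozen. A transition with
Hamiltonian error above 1000 counts as a divergence. Diagnostics are split
R-hat, bulk/tail ESS (arviz) and the divergence count; a fit is acceptable
iff max R-hat < 1.01 and no divergences. Seeded chains make every fit
reproducible. The reference budget is 4 chains × (5000 + 5000); tests and
examples use reduced budgets (hundreds of warm-up draws), which is why their
R-hat occasionally exceeds the strict 1.01 flag — flagged, never fatal.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
knob. Marginals are moment-matched to the published baseline table: SOFA is
beta-binomial on 0–24 (mean 8, intraclass ρ = 0.068, matching median 8 and
IQR 5–10 — a plain binomial is too narrow); lactate, PaO2:FiO2 and
norepinephrine dose among users are log-normal matched to the published
medians/IQRs (1.8 [1.1–3.2] mM, 15.8 [11.8–21.0] kPa, 0.20 [0.10–0.40]
µg/kg/min); vasopressor use is Bernoulli(0.547) with an exact point mass at
zero dose for non-users; COPD 19.5%, haematological malignancy 5.8%, open
system 28.6%. Outcomes follow a logistic model with configurable treatment
effect, covariate effects, interactions and Normal(0, 0.3) site intercepts;
the default baseline logit (−1.513) was calibrated once by simulation so the
default cohort's marginal mortality is ~42.5%, and default covariate effects
give severity gradients of the published magnitude (~32%→57% mortality over
the SOFA range). Allocation is permuted-block (block size 2) within
site × COPD × haematological-malignancy strata, so arm counts per stratum
never differ by more than one. Missingness is injected completely at random
at the published rates (SOFA 89/2888, lactate 19/2888, PaO2:FiO2 12/2888)
and only for SOFA, PaO2:FiO2 and lactate.

What the generator does *not* emulate: covariates are mutually independent
(the real joint distribution is unpublished), there is no longitudinal
oxygen exposure, no informative missingness, and site sizes are uniform.
Passing tests therefore demonstrate that the machinery recovers known truth
under the stated generative model — not that the real cohort's estimates are
reproduced, which would require the confidential data.

## Validation design choices

* **Coverage study** (200 trials, n = 2888, true β drawn from the weak
  prior): trials are simulated from the same model family the primary
  analysis fits (site intercepts plus COPD/haematological-malignancy
  effects, no continuous-covariate effects), because omitting prognostic
  covariates from a logistic model attenuates the conditional log-OR
  (non-collapsibility) and would confound a calibration check with a
  misspecification study. Reduced draws (2 chains × (200 + 250)) keep the
  study inside a normal test run; quantile Monte-Carlo noise at that budget
  is small relative to the 90–99% acceptance band.
* **Null-interaction calibration**: for a single simulated dataset the
  posterior P(interaction OR > 1) is itself approximately uniform across
  data realizations (it tracks the realized z-score of the interaction), so
  the check averages P(OR > 1) over 40 replicate null datasets of n = 20 000,
  which concentrates near 1/2 (SE ≈ 0.046) when the machinery is calibrated.
* **Shrinkage ordering**: partial pooling is compared against the no-pooling
  and complete-pooling *limits of the same hierarchical model* (pooling-SD
  prior scale 5.0 vs 1e-3), the standard three-way comparison. Comparing
  against separately fitted per-subgroup models instead is not a clean test
  of pooling: posterior medians of a correct hierarchical fit can sit
  slightly outside a separately fitted estimate through neighbor-group
  attraction and likelihood skew (confirmed by cross-checking the exact
  posterior with an independent Gibbs sampler), effects unrelated to the
  pooling mechanism under test. The simulated heterogeneity is bimodal
  (±0.5, 250 patients per group) so no subgroup's true effect coincides
  with the pooled mean and every shrinkage margin is resolvable above
  Monte-Carlo error.
* **Quadrature oracle**: the toy-model cross-check integrates the exact
  4-parameter posterior on a dense grid (41⁴ points spanning ±5 posterior
  SDs) after collapsing observations to covariate patterns.

## Known limitations

* The sampler is single-threaded pure numpy; it is sized for these models
  (≤ ~50 parameters, n ≤ tens of thousands), not a general PPL replacement.
* The missingness gate implements complete-case analysis only; at ≥5%
  missingness the pipeline aborts loudly rather than imputing.
* DerSimonian–Laird is the only τ² estimator (REML/Paule–Mandel are out of
  scope), and meta-analysis is on the OR scale only.
* Interaction models are linear on the log-OR scale by design; no splines or
  other flexible forms are offered, matching the emulated analysis plan.
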
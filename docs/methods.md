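# Methods

This note documents the model, the estimators, the synthetic world they are
validated on, and the numerical and design choices behind both.

## 1. Structural model

A resident allocates disposable income between composite consumption `c` and
medical care `m` under additively separable CRRA preferences

    U(c, m) = (1 − θ) c^(1−γ1)/(1−γ1) + θ m^(1−γ2)/(1−γ2),

with the log limit at a risk-aversion coefficient of 1.  The latent health
weight θ ∈ [0, 1] is the resident's private information; θ = 0 means no care
is demanded, θ near 1 means medical care dominates the utility trade-off.
Marginal utilities are positive and diminishing, cross-derivatives are zero,
and marginal utility diverges as either good goes to zero — so interior
solutions obtain whenever θ ∈ (0, 1).

Insurance changes only the budget: an insured resident pays the premium `p`
and an effective price `1 − a` per unit of care, where the realized
reimbursement rate `a` (reimbursed amount / gross expense) is uncertain at
decision time.  The resident maximizes expected utility over the conditional
density f(a | m) of the rate given the expense level.

### Latent-health inversion

Setting the m-derivative of expected utility to zero and solving for θ gives

    θ̂ = J / (J − m^(−γ2)),
    J  = ∫ [ −(1 − a) (y − p − m(1 − a))^(−γ1) f(a|m)
             + (y − p − m(1 − a))^(1−γ1)/(1−γ1) · ∂f(a|m)/∂m ] da.

J is the derivative of the expected composite-consumption felicity; the
textbook presentation multiplies through by (1 − γ1), which degenerates at
γ1 = 1 — working with J keeps the log-utility limit well defined (at γ1 = 1
the second integrand uses log(y − p − m(1 − a))).  Note the m-term is
m^(−γ2): it is the derivative of θ m^(1−γ2)/(1−γ2).  A variant with the
opposite exponent sign is retained behind `convention="printed"` for audit
purposes only.

Evaluation routes, per record:

* **KDE route** (insured records whose (year, service, tier) stratum has a
  fitted surface): trapezoidal quadrature over the 100-category rate grid,
  with f and ∂f/∂m interpolated to the record's m (linear in log m).
* **Degenerate route** (uninsured records, and fallback for thin strata):
  f(a|m) a point mass.  The FOC then has the closed form
  θ = r/(1 + r), r = (1 − a_marg)(y − p − m(1 − a₀))^(−γ1) m^(γ2), where a₀
  is the atom (the realized average rate) and a_marg the rate on the
  *marginal* unit of expense.  When the point mass tracks a known schedule
  a(m), the density-derivative term of J contributes exactly the difference
  between average and marginal rates, so using the schedule's marginal rate
  in the closed form reproduces the full integral (`route="policy"`).
  Uninsured residents use a₀ = a_marg = 0 and p = 0.
* m = 0 ⇒ θ̂ = 0; records with non-positive residual consumption anywhere
  the density has mass are excluded and counted (`infeasible`).

θ̂ is clipped to [0, 1] with a flag; the clip rate is reported per run.

## 2. Conditional density of the reimbursement rate

Per stratum (year × service type × hospital tier) with ≥ 30 insured
positive-expense records, f(a | m) is a product-Epanechnikov kernel
estimator on a grid of 100 equally spaced rate categories on [0, 1] and 100
log-spaced expense knots spanning the stratum's observed range.

* **Atom at a = 0.**  Below-deductible and uncovered claims produce a point
  mass at zero that a continuous KDE cannot carry.  Default treatment
  (`atom="mixture"`): the atom weight π₀(m) is the kernel-weighted frequency
  of a = 0, and the continuous part is a reflected KDE of the positive
  rates; the mixture is renormalized per slice.  On the discrete grid the
  atom sits on the first knot with its trapezoid weight.  A pure-KDE
  fallback (`atom="kde"`) is available for comparison.
* **Boundaries.**  The rate kernel is reflected at 0 and 1.
* **Bandwidths.**  Robust Silverman rule 0.9·min(sd, IQR/1.34)·n^(−1/5),
  multiplied by the Epanechnikov canonical factor 1.7188 so a rule derived
  for Gaussian kernels transfers; or least-squares cross-validation over a
  geometric candidate grid (default Silverman × [1/3, 3], ties toward the
  smaller bandwidth).  The LSCV leave-one-out term excludes *all* exact
  copies of each point: with heaped amounts (here, agents bunching exactly
  at cap-exhaustion kinks) the classical criterion diverges to −∞ as h → 0,
  and leaving out duplicates is the standard remedy; on continuous samples
  the modification is a no-op.
* **Derivative.**  ∂f/∂m by central finite differences across expense knots
  (one-sided at the ends) — second-order accurate on smooth surfaces.
* **Floors.**  Expense knots whose marginal density falls below
  1e−12 × max are given the uniform conditional slice rather than 0/0.

## 3. Subgroup risk aversion by moment matching

(γ1, γ2) is assumed constant within each of the four gender × education
subgroups (high = high school or above).  Identification uses the
assumption that each subgroup's θ distribution is stable across the two
waves: at the true pair, θ̂ applied to both waves yields equal moments, while
wave-level shifts in observables (income growth, the premium rise, the
changing mix of below-deductible / interior / above-cap records) distort the
two waves differently at wrong pairs.  The estimator minimizes the unweighted
sum of squared differences in mean, variance, skewness and kurtosis
(standardized central moments; normal kurtosis = 3) over an equally spaced
grid on [1, 9]², with ties broken toward the lexicographically smallest
node.  Results are reported for 20×20, 40×40 and 50×50 grids and their
average.  Bootstrap SEs resample residents with replacement within
subgroup × wave and re-run the full grid search per replicate (default
B = 100); replicates with degenerate moments are dropped and counted, > 20%
failures flags the SEs unreliable.

The FOC integral depends on γ1 only, so the evaluator caches it per record
per γ1 node; grid search and bootstrap reuse one pass over the data.

**Identification caveat (important).**  The moment objective has a soft
ridge along proportional rescalings of (γ1, γ2): wrong pairs on the ridge
distort both waves almost identically, and the residual signal (the
wave-to-wave shift in the marginal-rate composition) is small relative to
the sampling noise of the kurtosis difference between two independent
n ≈ 5,000 draws.  The estimator is consistent — at n = 40,000/wave the
argmin moves decisively toward the truth — but at survey-scale samples its
bootstrap SEs are of order 1–2 grid units, concentrated along the ridge.
This matches the magnitude of the uncertainty such grouped moment designs
report in practice, and it is why the package always reports bootstrap SEs
next to point estimates.

## 4. Adverse selection

Latent health of insured vs uninsured is compared by the one-sided
two-sample Kolmogorov–Smirnov statistic D = sup_x [F̂_unins(x) − F̂_ins(x)]
(insured CDF below ⇔ insured stochastically sicker), evaluated at all
pooled points with ties handled insured-first so the supremum equals the
block-end ECDF difference.  Two p-values are available:

* `asymptotic`: exp(−2 D² n_e), n_e = n₁n₂/(n₁+n₂) — the classical
  one-sided tail, which assumes continuous distributions.  Under the θ = 0
  atom it is conservative (empirical size ≈ 0.02 at nominal 0.05 in our
  simulations).
* `permutation` (seeded): exact under exchangeability, recommended whenever
  the samples contain ties; this is what the calibration tests use.

A two-sided alternative (for wave-stability checks of observed health
scores) uses the Kolmogorov asymptotic tail or the same permutation scheme.

## 5. Moral hazard via Slutsky decomposition

For each insured resident with observed (m₁, a₁):

* m₂: demand at price 1 on the compensated budget y − p + a₁m₁ (the
  compensating variation that keeps the observed bundle exactly affordable);
* m₃: demand at price 1 on budget y − p;
* m₄: demand at price 1 on budget y (uninsured scenario).

m₁ − m₂ ≥ 0 is the substitution effect — over-consumption attributable to
the insurance-lowered price (mixing demand-side and supplier-side
responses); m₃ − m₂ and m₄ − m₂ are both reported as income-effect readings
(they differ by the premium channel), and the identity
m₁ − m₄ = (m₁ − m₂) + (m₂ − m₄) holds by construction.

The θ entering the counterfactual problems is the degenerate closed form at
the realized rate a₁ — the latent weight that rationalizes the observed
bundle at the price the resident actually faced.  This choice guarantees
the compensated law of demand record by record (m₂ ≤ m₁, strict whenever
a₁m₁ > 0 and θ ∈ (0, 1)); a θ̂ from another route (e.g. the KDE surface) can
violate it for records whose observed bundle it does not rationalize.  A
side effect worth knowing: because θ is re-inverted from the observed m₁,
a provider-side shift that scales m₁ (such as a payment reform) is largely
reabsorbed into θ̂, so the over-consumption *share* is nearly invariant to
such shifts in the deterministic synthetic world.

Incidence is the fraction of all insured residents whose over-consumption
exceeds 1e−9·m₁; descriptive blocks (mean/min/max/sd of actual,
counterfactual, over-consumption, share) are computed over the
over-consuming subset per wave.  Heterogeneity is summarized by paired
ECDFs of the share split by age ≥ 65, income above the mean, education,
latent health above the mean, exercise, smoking, gender, and marital
status, with the maximum vertical gap reported.

Demand at price 1 solves the monotone FOC
(1 − θ)c^(−γ1) = θ(W − c)^(−γ2) by fixed-count bisection in log space
(80 iterations; relative precision far below 1e−12), with θ = 0 ⇒ m = 0 and
θ = 1 guarded by a numerical floor on c.

## 6. Payment-reform evaluation (PSM-DID)

Reform rollout is province-level and non-random, so a logit propensity of
treatment-group membership is fitted on individual covariates (age, gender,
income, education, marital status, children, latent health, five health
habits) and province covariates (medical staffing, GP density, beds, log
GDP per capita, two insurance-fund revenue/expenditure ratios).  Each
treated resident is matched 1:1 to the nearest-propensity control within
the common support (with replacement by default; a caliper and
without-replacement matching are available), separately per year so both
periods stay represented.  Standardized mean differences before/after and
support bounds are reported.

The DID regression on the matched sample is

    Y = α0 + α1 Treat×Post + β Treat + controls + year FE + ε,

by OLS with standard errors clustered on province.  The Treat main effect
is always included — without it, treatment-correlated province levels load
onto the interaction; with it (and no controls) α̂1 is exactly the 2×2
cell-mean DID.  Collinear columns are dropped and reported.  Expenditure
outcomes are modeled as log1p (coefficients read as semi-elasticities); the
over-consumption share is kept in levels.

`simulate_reform_panel` provides reduced-form two-period fixtures with a
known effect: a clean variant (parallel trends hold; used for bias checks)
and a confounded variant in which a covariate is both shifted in treated
provinces and carries a period-varying outcome loading — there the
unmatched DID is biased by construction and matching removes most of the
bias.  Its residual noise is deliberately small (sd 0.10) so an n = 10,000
design resolves bias at the 0.01 level; it is a correctness fixture, not a
calibration to real expenditure dispersion.

## 7. The synthetic world

`generate_population` draws two waves (2020, 2022) of residents:

* θ: point mass at 0 with probability 0.6 plus Beta(1.2, 1.8) on (0, 1] —
  about 60% of residents demand no care in a year, matching the share of
  non-users in resident-scheme survey data; the mixture is identical across
  waves (the identification assumption of §3 holds by construction).
* Incomes: log-normal with sdlog 1.0, floored at 3,000, means ≈ 31,400
  (wave 1) and ≈ 38,900 (wave 2) — the observed income level and growth of
  the study population; a province loading correlates incomes with province
  development.
* Premiums: 250 (wave 1) and 380 (wave 2), the national average resident
  premiums in those years.
* Enrollment: logistic in θ (slope +2.0 — adverse selection) and mildly
  decreasing in log income, calibrated to ≈ 86% coverage.
* Schedule: general outpatient covered only at primary hospitals (50%,
  cap 500); inpatient covered at all tiers with rates 80/70/60%,
  deductibles 400/400/1,000 and cap 250,000.  Chronic-outpatient entries
  are supported but not generated by default.
* Behaviour: every agent's m maximizes realized utility given their budget.
  Insured demand solves the kinked problem by a 2,000-point log-spaced grid
  on (0, 0.95·(y − p)] plus golden-section refinement, then snaps to
  schedule kink points when they attain the maximum — bunching at the
  cap-exhaustion expense is exact, as the theory implies.  Uninsured (and
  uncovered) demand uses the closed-form FOC.
* Subgroup (γ1, γ2): (4.07, 5.96), (5.28, 7.15), (5.19, 6.82), (5.72, 7.94)
  for male/female × low/high education — medical-care risk aversion above
  composite-goods risk aversion in every subgroup.
* Reform: 21 of 31 provinces are treated (selection correlated with
  province development), and treated-post insured expenditures are scaled
  by exp(−0.10) after the behavioural stage — a reduced-form overlay
  representing provider-side restraint, deliberately off the residents' FOC.
* Optional jitter (truncated normal, default sd 0.05 in the pipeline demo)
  perturbs positive realized rates to emulate the dispersion of real
  reimbursement data and give the KDE stage something nondegenerate to
  estimate; the deterministic world (jitter 0) is what the exact recovery
  tests use.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: household structure, dynamic health
evolution, measurement error in expenditures and incomes (real survey
amounts are heaped and recalled, which *smooths* empirical expense
densities — our noiseless optimizer instead produces hard structural
features such as the below-deductible mass and the demand gap above
high-tier deductibles, on which bandwidth selectors legitimately disagree
more than they do on real data), city-level rollout granularity, supplier
behaviour beyond the scalar reform overlay, and any calibration of
higher-order moments to the real microdata.

## 8. Numerical choices and degenerate inputs

* Odds and FOC computations are done in logs to avoid overflow at large
  m^γ; θ = r/(1+r) is evaluated as a sigmoid of log r.
* Bandwidth rules raise on samples whose spread is below 1e−12 of their
  magnitude (float residue of constant samples is not spread); the rate
  dimension falls back to a narrow 0.02 bandwidth for degenerate positive
  rates.
* Grid-search ties break lexicographically; bootstrap replicates are fully
  determined by (data, grid, seed).
* Slutsky results clip negative over-consumption at the solver tolerance;
  zero-expense records are carried with m₂ = m₁ = 0 and excluded from the
  over-consuming descriptive block.
* All randomness flows from a single integer seed per run; artifacts are
  written with round-trip float precision so cached and fresh runs agree
  bit for bit.

## 9. Problem sizes used by the test suite and acceptance script

Unit and property tests run on worlds of 1,500–5,000 residents per wave;
the density convergence checks use up to 20,000 draws; the dominance-test
calibration uses 2,000 replicates of 500 + 500 samples with 199
permutations each; the reform fixtures use 10,000 residents per period; and
the acceptance script runs the full pipeline at 4,000 residents per wave
with 100 bootstrap replicates per grid.  These sizes were chosen so each
check has the statistical resolution its tolerance requires.
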
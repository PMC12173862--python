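# Methods

## Scoring model

All three indices operate on per-capita daily intakes over twelve food
groups (sugar, sweets and soft drinks deliberately excluded: they add
"diversity" without diet quality). Intakes are household totals divided by
ledger person-days rather than by household size: the meal ledger counts
person-meals actually eaten at home (family and guests), so
`person_days = person_meals / meals_per_day` corrects for eating away from
home and for guests. A household with zero person-meals or zero total
intake has undefined indices; such households are excluded with a logged
reason code, never scored 0 — an index of 0 is a meaningful (maximally poor)
diet, not a missing one.

- **EI** is Shannon entropy in nats of the 12 weight shares, with
  `0·ln 0 ≡ 0`. Natural log is used so the maximum is `ln 12 ≈ 2.48`. EI is
  invariant to rescaling all grams.
- **CFPS** aggregates the 12 groups into the Pagoda's 8 categories
  (cereals/tubers/dried legumes → grains tier; fungi/algae → vegetables;
  meat + poultry merged; the mapping is configurable) and applies the
  three-tier rule per category. The full-credit band takes precedence where
  the half-credit clauses overlap it (an intake just inside `L` also
  satisfies `|intake − L| ≤ 0.5L`); half credit applies only outside the
  band within 50% relative distance of a bound.
- **CHEI** (0–60 equal-weight variant) sums twelve 5-point components.
  Limitation scoring is continuous: the linear ramp reaches exactly 0 at
  the cut-off `U`, so scoring `intake ≥ U` as 0 creates no discontinuity.
  The default component table classifies all twelve groups as adequacy
  components (no authoritative limitation designation exists for this
  12-group variant); limitation components are fully supported via the
  `component,kind,R,L,U` CSV. The shipped bounds are seeded from the 2016
  Chinese Dietary Pagoda recommended ranges and are editable — every test
  and property depends on the rule structure, not the specific gram values.

## Synthetic survey generator

The generator emulates a stratified multi-stage design — provinces →
counties → townships → villages → households (default 3 × 4 × 3 × 3 × 10 =
1,080 households, 108 villages, 12 counties) — over 3 survey days.

Covariate marginals are calibrated to the survey-style descriptive targets
in `Calibration` (money in 10⁴ Yuan, land in ha, distances in km):
right-skewed non-negative variables (income, property, distances, village
population/land) are log-normal matched to mean and SD; binary
decision-maker traits are Bernoulli; dietary knowledge is Binomial(9, ·);
household size is 1 + Poisson; pension is zero-inflated log-normal;
off-farm share is Beta matched to mean and SD.

**Age composition** uses a two-level mixture: a household is *elderly-type*
with probability `p_elderly / 0.75` and its members are elderly with
probability 0.75; other households mix children (probability
`p_child / (1 − q_e)`) and adults. Marginally each member is elderly with
probability `p_elderly` and a child with probability `p_child`, so the mean
shares hit their targets exactly, while concentrating elderly members in
elderly-type households reproduces the large between-household dispersion
of the elderly share (SD ≈ 40 percentage points) that an iid-member model
badly understates (≈ 29). The three published component means sum to 99.24
rather than 100 (a rounding artifact of the source table); the mixture
weights are those means renormalized. The child-share SD comes out ≈ 18.6
vs the published 15.36 — the single-parameter family cannot match all three
component SDs simultaneously, and the elderly share (the aging measure) is
prioritised.

**Planted effects.** For each of EI and CHEI, a target index value is drawn
from `intercept + β_u18·ratio_u18 + β_o65·ratio_o65 + γ·income +
Σ controls + county effect + noise` (county effects iid normal; EI targets
clipped to (0, ln 12), CHEI to (0, 60); defaults place the clips ≥ 3.7σ
from the mean so truncation bias is negligible). Consumption is then
synthesised *backwards* from the targets through two dials:

1. **Evenness dial.** Weight shares come from the geometric family
   `wᵢ(t) ∝ exp(−t·i)`, whose entropy decreases monotonically from ln 12 at
   `t = 0`; `t` is solved by vectorised bisection so the shares' entropy
   equals the EI target exactly, then the 12 positions are randomly
   permuted (entropy-invariant).
2. **Quantity dial.** The total per-capita quantity `T` is solved by
   bisection so the adequacy-component CHEI of `T·w` equals the CHEI target
   exactly (the score is continuous and non-decreasing in `T`, reaching 60
   at `T = maxᵢ Rᵢ/wᵢ`).

Re-scoring generated data therefore reproduces the planted EI and CHEI to
machine precision, and downstream OLS recovers the planted coefficients
with nominal coverage. CFPS is **emergent**: two dials cannot encode three
independent index targets, so the Pagoda score inherits its variation from
the shares and scale. A CFPS `EffectSpec` is accepted but triggers a
warning rather than being planted.

Default planted coefficients follow the sign pattern of the main survey
regression (elderly share negative, income positive, dietary knowledge
positive), with intercepts chosen so the implied index means sit near the
descriptive means (EI ≈ 1.26, CHEI ≈ 23.15) and noise SDs chosen so total
index SDs match (≈ 0.30 and ≈ 6.2).

Household totals are split across survey days by a Dirichlet(5,5,5) draw;
at-home family meals are Binomial(size × 3, 0.9) per day and guest meals
Poisson(0.5) — guests exist purely to exercise the standardization. All
randomness flows from one `numpy` Generator; identical seeds give
byte-identical CSVs.

**What the generator does not emulate:** the true joint distribution of the
unpublished survey (only marginals and planted linear effects), within-day
meal composition, spatial structure, eating-away-from-home imputation
(only at-home consumption is produced), and any genuine correlation
between covariates beyond the composition mixture. Passing tests therefore
demonstrate that the *pipeline* is correct and well-calibrated, not that
the real survey's coefficients are reproduced.

## Inference

- **Main model:** OLS of an index on the under-18 and over-65 ratios
  (18–65 omitted as reference), income, and the full control set, with
  county dummies. Standard errors use the cluster sandwich with the
  `G/(G−1)·(n−1)/(n−k)` correction. With one observation per household,
  household-level clustering *is* HC1 (the correction reduces to
  `n/(n−k)`), so the cluster factor is configurable (household / village /
  county; default household). Rows with any missing field are dropped and
  counted. Rank-deficient designs either raise or drop dependent columns
  greedily left-to-right (intercept and focal regressors take precedence).
- **Heterogeneity:** the main model re-fit per stratum
  (tercile / median / custom thresholds; minimum stratum size 30). When
  the sample is split into *income terciles*, income is removed from the
  within-stratum regressor list; `include_split_var` overrides either way.
- **SUR:** one-step feasible GLS — per-equation OLS, residual covariance
  `Σ̂ = E'E/n`, then GLS on the stacked system assembled blockwise
  (`(Σ̂⁻¹)_{gh} X_g'X_h`), no iteration, hence deterministic. With
  identical regressor matrices FGLS equals per-equation OLS (the textbook
  identity used as a test oracle). A singular `Σ̂` (condition number
  > 10¹²) triggers a per-equation-OLS fallback with a warning. The joint
  Wald test for a regressor across all `G` equations is
  `β' V⁻¹ β ~ χ²(G)` using the stacked GLS covariance.
- **LASSO:** parameterised directly in the raw objective
  `RSS + λΣ|β|` (the solver is scikit-learn's coordinate descent, called
  with `α = λ/(2n)`, which makes the two objectives exactly proportional).
  Predictors are standardized once on the full sample (mean 0, SD 1);
  the grid is 100 log-spaced values from `λ_max = 2·max|x'y|` down to
  `10⁻⁴ λ_max`; folds are a seeded permutation of `i mod k`; selection is
  CV-MSE-minimizing λ with a one-standard-error-rule option. Coefficients
  are reported on both standardized and original scales.

Significance stars follow the economics convention (* p<0.1, ** p<0.05,
*** p<0.01). Descriptive tables use the sample SD (n−1). Log transforms
use `ln(1+x)` throughout for variables with legitimate zeros (pension,
distances, land, village income/land).

## Projection

Drivers follow geometric recursions (`ratio_t = ratio_{t−1}(1+m)`,
`income_t = income_{t−1}(1+n)`); each index is the exact linear evaluation
`y_t = α + β₃·ratio_t + γ·income_t` per year. The default aging rate is
m = 0.0103 and income scenarios n ∈ {0, 0.025, 0.05, 0.075}. A
`linear-increment` mode adds `100·m` percentage points of elderly share
(and fraction `n` of start income) per year, because a "1.03% per year"
aging rate reads either way and the two modes diverge substantially by
2050 (≈ 26% vs ≈ 48% elderly from a 20% start); neither is endorsed and
both can be reported side by side. Projections are unconstrained linear
extrapolations by default; clipping to the indices' admissible ranges
([0, ln 12] / [0, 8] / [0, 60]) is optional. The elderly share is always
capped at 100% with a warning. Coefficients typically come from a fitted
`RegressionFit` via `coefficients_from_fit`, or can be supplied directly.

## Numerical choices and test design

- Bisection tolerances: 64 iterations on bracketed monotone functions
  (entropy ≈ 1e-15 relative; CHEI scale ≈ 1e-10 absolute).
- The independently coded sandwich formula, the SUR=OLS identity and the
  soft-threshold closed form `β̂ = sign(b)·max(|b| − λ/2, 0)` (unit-norm
  predictor) serve as test oracles and are never the implementation path.
- Monte-Carlo suites: test-size calibration of the elderly-share t-test
  uses 1,000 noise-only replicates on fixed covariates from one default
  survey (band 3.5–6.5% at the 5% level); SUR Wald calibration uses 1,000
  replicates of 8 pure-noise outcomes at n = 300 against χ²(8) tail
  frequencies within 3 MC SEs; parameter recovery runs 200 full
  generate→score→fit replicates at the default n = 1,080 (sign recovery of
  the planted elderly/income effects on EI; 95% CI coverage within 3 MC
  SEs of nominal for all six focal coefficients of EI and CHEI). The
  generator's vectorisation keeps one full replicate near 0.1 s, so the
  whole suite runs in a few minutes on one CPU.

## Known limitations

- The CHEI backward synthesis assumes the generator's default all-adequacy
  component table; planting CHEI targets under custom limitation-heavy
  tables would need a non-monotone solver.
- The emergent CFPS mean (~1.1) sits below the published descriptive mean
  (1.99); only EI and CHEI moments are directly calibrated.
- Cluster-robust inference with household clusters is exactly HC1;
  genuinely clustered designs (village/county) are supported but the
  default survey plants no within-village error correlation.
- LASSO standardization uses full-sample moments rather than
  fold-internal moments; with n ≫ p this changes CV error negligibly.
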
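# ruraldiet

Dietary-health analysis of rural household food-consumption surveys:
simulation, index scoring, regression inference and scenario projection.

Rural Chinese household surveys commonly record all food eaten at home over
three consecutive days, plus a meal ledger (how many person-meals family
members and guests actually ate at home), household age composition and
income, and a battery of decision-maker / household / village covariates.
`ruraldiet` implements the full analysis chain for such data, aimed at
nutrition economists and epidemiologists who want to study how family
composition (especially population aging) and income shape dietary health —
and who need a faithful synthetic data generator because survey microdata
of this kind are rarely public.

## What it computes

**Standardization.** Household grams are divided by ledger-implied
person-days, `person_days = (family + guest person-meals) / meals_per_day`,
correcting for meals eaten away from home.

**Three dietary-health indices** from per-capita intakes over twelve food
groups (cereals, tubers, dried legumes, vegetables, fungi/algae, fruits,
nuts/seeds, meat, poultry, dairy, eggs, aquatic products):

- **Entropy Index (EI)** of dietary diversity:
  `EI = -Σᵢ wᵢ ln wᵢ`, with `wᵢ` the share of total edible weight in group
  *i*; ranges 0 (one food only) to ln 12 ≈ 2.48 (perfectly even).
- **Chinese Food Pagoda Score (CFPS)**, guideline adherence over the
  Pagoda's eight core categories: per category `sⱼ = 1` if
  `Lⱼ ≤ intakeⱼ ≤ Uⱼ`, `0.5` if outside the band but within 50% relative
  distance of either bound, else 0; `CFPS = Σⱼ sⱼ ∈ [0, 8]`.
- **Chinese Healthy Eating Index (CHEI, 0–60 equal-weight variant)**:
  twelve 5-point components; adequacy components score
  `min(intake/R, 1)·5`, limitation components score 5 at or below the ideal
  limit `L`, ramp linearly to 0 at the cut-off `U`.

**Inference.** The main model
`yᵢ = α + Σⱼ βⱼ ratioⱼᵢ + γ·incomeᵢ + θ'Zᵢ + εᵢ`
(county fixed effects, cluster-robust sandwich SEs, the 18–65 ratio as the
omitted reference), heterogeneity splits (tercile/median/custom),
an eight-equation SUR system over Pagoda-category quantities with joint
chi-square Wald tests, and an L1-penalised robustness check
(`min_β Σᵢ(yᵢ − xᵢ'β)² + λΣⱼ|βⱼ|`, λ by 10-fold cross-validation).

**Projection.** `y_t = α + β₃·ratio_t + γ·income_t` with the elderly share
compounding at rate *m* and income at rate *n*
(`ratio_t = ratio_{t−1}(1+m)`), across income-growth scenarios
n ∈ {0, 2.5, 5, 7.5}%.

**Synthetic surveys.** `generate_survey` emulates a stratified design
(3 provinces × 4 counties × 3 townships × 3 villages × 10 households =
1,080 households in 108 villages by default) with covariate marginals
calibrated to published descriptive statistics and *planted* index effects:
target EI and CHEI values are drawn from linear models, then consumption
records are synthesised that reproduce those targets exactly when
re-scored, so downstream regressions recover the planted coefficients.

## Worked example

```python
from ruraldiet import (RegressionSpec, fit_main_model, generate_survey,
                       score_dataset)

data = generate_survey(seed=1)                       # 1,080 households
res = score_dataset(data.consumption, data.meals)    # EI, CFPS, CHEI
merged = res.scores.merge(data.covariates, on="household_id")
fit = fit_main_model(merged, RegressionSpec(outcome="EI"))
print(fit.table().set_index("term").loc[["ratio_over65", "income"]])
```

prints (seed 1):

```
  ratio_over65: -0.0008 (0.0002) ***
        income: +0.0157 (0.0025) ***
```

i.e. each additional percentage point of household members aged 65+ lowers
the diversity index by ~0.001 nats while each additional 10⁴ Yuan of
per-capita income raises it by ~0.016 — recovering the generator's planted
effects (−0.001 and +0.017) within two standard errors. The scored dataset
itself averages EI ≈ 1.28, CFPS ≈ 1.05, CHEI ≈ 22.6, matching the
calibration targets. Longer narratives live in `examples/`
(`simulate_survey.py`, `score_diet.py`, `fit_regressions.py`,
`project_trends.py`, `run_pipeline.py`), and a thin CLI wraps the pipeline:

```bash
ruraldiet simulate --seed 1 --out run/
ruraldiet score --records run/consumption.csv --meals run/meals.csv --out run/scores.csv
ruraldiet all --seed 1 --outdir run/
```

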
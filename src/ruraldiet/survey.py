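"""Synthetic household food-consumption survey generator.

Emulates a stratified multi-stage sampling design (provinces -> counties ->
townships -> villages -> households) with a 3-day at-home food record, a
meal ledger and a full household/village covariate sheet whose marginal
moments are calibrated to the survey's descriptive statistics.

Index effects are *planted*: a target Entropy Index and a target
healthy-eating index are first drawn from linear models in the household
covariates (plus county effects and noise), then a consumption pattern is
synthesised that reproduces those targets exactly when re-scored — the
12-group weight shares come from a one-parameter geometric family whose
Shannon entropy is solved to match the EI target, and the total per-capita
quantity is solved so the adequacy-component healthy-eating score matches
its target.  The Pagoda score is emergent from the same grams (two dials
cannot encode three independent targets).  Downstream regressions therefore
recover the planted coefficients up to sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .foods import FOOD_GROUP_NAMES, N_FOOD_GROUPS, FoodGroup, load_chei_components
from .indices import LN12

logger = logging.getLogger(__name__)

INDEX_NAMES = ("EI", "CFPS", "CHEI")

#: Regressor columns derivable from a covariates sheet (log transforms use
#: ln(1+x) for zero-heavy variables).
DERIVED_REGRESSORS = (
    "gender_dm", "married_dm", "education_dm", "dki",
    "ln_pension", "off_farm", "ln_distance", "ln_land",
    "crop_diversity", "household_size", "property",
    "village_population", "village_distance", "food_market_density",
    "ln_village_income", "ln_village_land",
)


@dataclass(frozen=True)
class SurveyDesign:
    """Stratified sampling design; the default reproduces the study layout
    of 3 provinces x 4 counties x 3 townships x 3 villages x 10 households
    surveyed over 3 consecutive days (1,080 households in 108 villages)."""

    provinces: int = 3
    counties_per_province: int = 4
    townships_per_county: int = 3
    villages_per_township: int = 3
    households_per_village: int = 10
    days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "provinces", "counties_per_province", "townships_per_county",
            "villages_per_township", "households_per_village", "days",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_counties(self) -> int:
        return self.provinces * self.counties_per_province

    @property
    def n_villages(self) -> int:
        return self.n_counties * self.townships_per_county * self.villages_per_township

    @property
    def n_households(self) -> int:
        return self.n_villages * self.households_per_village


@dataclass(frozen=True)
class EffectSpec:
    """Planted linear-model coefficients for one outcome index.

    ``beta_under18`` / ``beta_over65`` are per-percentage-point effects of
    the respective age-composition ratios; ``gamma_income`` is per 10^4 Yuan
    of per-capita income; ``control_betas`` maps derived regressor names to
    effects; ``county_sd`` is the SD of i.i.d. normal county effects.
    """

    intercept: float
    beta_under18: float = 0.0
    beta_over65: float = 0.0
    gamma_income: float = 0.0
    control_betas: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    county_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        unknown = set(self.control_betas) - set(DERIVED_REGRESSORS)
        if unknown:
            raise ValueError(f"unknown control covariates: {sorted(unknown)}")


#: Default planted effects: sign pattern of the study's main regression
#: (elderly share erodes, income improves, dietary knowledge improves all
#: indices), intercepts chosen so implied index means sit near the survey's
#: descriptive means (EI ~ 1.26, CHEI ~ 23.15).
DEFAULT_EFFECTS: dict[str, EffectSpec] = {
    "EI": EffectSpec(
        intercept=1.14, beta_under18=0.002, beta_over65=-0.001,
        gamma_income=0.017, control_betas={"dki": 0.012},
        noise_sd=0.28, county_sd=0.05,
    ),
    "CHEI": EffectSpec(
        intercept=20.83, beta_under18=0.006, beta_over65=-0.016,
        gamma_income=0.139, control_betas={"dki": 0.329},
        noise_sd=6.0, county_sd=1.0,
    ),
}


@dataclass(frozen=True)
class Calibration:
    """Marginal-moment targets for covariate generation (survey descriptive
    statistics; money in 10^4 Yuan, land in ha, distances in km)."""

    # published composition means (9.17 / 63.46 / 26.61 %) sum to 99.24;
    # mixture weights are those means renormalized to 1
    p_child: float = 0.0917 / 0.9924
    p_adult: float = 0.6346 / 0.9924
    p_elderly: float = 0.2661 / 0.9924
    # elderly members cluster in elderly-type households (retired couples):
    # a household is elderly-type with prob p_elderly/elderly_member_prob and
    # its members are elderly with prob elderly_member_prob, which keeps the
    # mean share at p_elderly while matching the published share SD (~39%)
    elderly_member_prob: float = 0.75
    income_mean: float = 2.53
    income_sd: float = 2.51
    mean_household_size: float = 3.16
    p_female_dm: float = 0.78
    p_married_dm: float = 0.91
    p_college_dm: float = 0.03
    dki_mean: float = 7.11
    pension_mean: float = 0.19
    pension_p_positive: float = 0.30
    off_farm_mean: float = 0.35
    off_farm_sd: float = 0.32
    distance_mean: float = 3.02
    distance_sd: float = 3.80
    land_mean: float = 0.34
    land_sd: float = 0.44
    crop_diversity_mean: float = 5.66
    property_mean: float = 16.09
    property_sd: float = 36.52
    village_population_mean: float = 900.95
    village_population_sd: float = 616.59
    village_distance_mean: float = 5.45
    village_distance_sd: float = 5.77
    food_market_density_mean: float = 13.73
    food_market_density_sd: float = 10.94
    village_income_mean: float = 1.63
    village_income_sd: float = 0.61
    village_land_mean: float = 322.73
    village_land_sd: float = 313.15
    guest_meal_rate: float = 0.5
    p_meal_at_home: float = 0.9

    def __post_init__(self) -> None:
        s = self.p_child + self.p_adult + self.p_elderly
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"age-class probabilities must sum to 1, got {s}")
        if not (0 < self.elderly_member_prob <= 1):
            raise ValueError("elderly_member_prob must be in (0, 1]")
        if self.p_elderly / self.elderly_member_prob >= 1:
            raise ValueError("p_elderly / elderly_member_prob must be < 1")
        for name in ("income_mean", "income_sd", "mean_household_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SurveyData:
    """One generated survey: raw records, meal ledger and covariates."""

    consumption: pd.DataFrame
    meals: pd.DataFrame
    covariates: pd.DataFrame
    design: SurveyDesign
    effects: dict[str, EffectSpec]
    true_index: pd.DataFrame  # household_id + planted EI / CHEI targets

    def write_csv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("consumption", self.consumption),
            ("meals", self.meals),
            ("covariates", self.covariates),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        return paths


# ---------------------------------------------------------------------------
# building blocks


def composition_from_ages(ages: Sequence[int]) -> tuple[float, float, float]:
    """Percentage shares of members aged <18, 18-64 and >=65."""
    if len(ages) < 1:
        raise ValueError("household must have at least one member")
    a = np.asarray(ages)
    n = len(a)
    child = float((a < 18).sum()) / n * 100
    elderly = float((a >= 65).sum()) / n * 100
    return (child, 100.0 - child - elderly, elderly)


def _draw_ages(
    rng: np.random.Generator, sizes: np.ndarray, cal: Calibration
) -> tuple[np.ndarray, np.ndarray]:
    """Integer member ages for households of the given sizes.

    A two-level mixture: a household is elderly-type with probability
    p_elderly / elderly_member_prob (its members elderly with probability
    elderly_member_prob, adults otherwise); other households mix children
    and adults.  Marginally each member is elderly with probability
    p_elderly and a child with probability p_child, while the elderly share
    concentrates within elderly-type households, reproducing the large
    between-household dispersion of the share.
    """
    n_hh = len(sizes)
    total = int(sizes.sum())
    q_e = cal.p_elderly / cal.elderly_member_prob
    c_prime = cal.p_child / (1.0 - q_e)
    if c_prime > 1:
        raise ValueError("infeasible calibration: child share too large for mixture")
    eld_hh = rng.random(n_hh) < q_e
    hh_of_member = np.repeat(np.arange(n_hh), sizes)
    u = rng.random(total)
    cls = np.where(
        eld_hh[hh_of_member],
        np.where(u < cal.elderly_member_prob, 2, 1),
        np.where(u < c_prime, 0, 1),
    )
    ages = rng.integers(np.array([0, 18, 65])[cls], np.array([18, 65, 91])[cls])
    return ages, hh_of_member


def plant_composition(
    household_size: int,
    age_distribution: Calibration | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Draw integer member ages for one household and return the implied
    percentage composition (sums to 100)."""
    if household_size < 1:
        raise ValueError("household_size must be >= 1")
    cal = age_distribution or Calibration()
    rng = rng or np.random.default_rng()
    ages, _ = _draw_ages(rng, np.array([household_size]), cal)
    return composition_from_ages(ages)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _entropy_of_geometric(t: np.ndarray) -> np.ndarray:
    """Shannon entropy of shares w_i proportional to exp(-t*i), i = 0..11."""
    i = np.arange(N_FOOD_GROUPS)
    logits = -t[:, None] * i[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(w > 0, -w * np.log(w), 0.0)
    return terms.sum(axis=1)


def shares_for_entropy(target: np.ndarray, iters: int = 64) -> np.ndarray:
    """12-group weight shares with the requested Shannon entropy.

    Uses the geometric family w_i(t) ~ exp(-t*i), whose entropy decreases
    monotonically from ln 12 at t = 0; t is solved by bisection.
    """
    target = np.clip(np.asarray(target, dtype=float), 1e-6, LN12 - 1e-9)
    lo = np.zeros_like(target)
    hi = np.full_like(target, 80.0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        h = _entropy_of_geometric(mid)
        too_even = h > target  # entropy decreasing in t: need larger t
        lo = np.where(too_even, mid, lo)
        hi = np.where(too_even, hi, mid)
    t = 0.5 * (lo + hi)
    i = np.arange(N_FOOD_GROUPS)
    logits = -t[:, None] * i[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def scale_for_chei(
    w: np.ndarray, target: np.ndarray, R: np.ndarray, iters: int = 64
) -> np.ndarray:
    """Total per-capita quantity T such that the adequacy-only healthy-eating
    score of the intake vector T*w equals ``target`` (bisection; the score is
    continuous and non-decreasing in T, reaching 60 at T = max_i R_i/w_i)."""
    target = np.clip(np.asarray(target, dtype=float), 0.1, 59.9)
    hi = (R[None, :] / w).max(axis=1) * 1.01
    lo = np.zeros_like(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        score = (np.minimum(mid[:, None] * w / R[None, :], 1.0) * 5.0).sum(axis=1)
        lo = np.where(score < target, mid, lo)
        hi = np.where(score < target, hi, mid)
    return 0.5 * (lo + hi)


def derive_regressors(covariates: pd.DataFrame) -> pd.DataFrame:
    """Regressor frame from a covariates sheet (adds ln(1+x) transforms)."""
    z = covariates.copy()
    z["ln_pension"] = np.log1p(z["pension"])
    z["ln_distance"] = np.log1p(z["distance_km"])
    z["ln_land"] = np.log1p(z["land_ha"])
    z["ln_village_income"] = np.log1p(z["village_income"])
    z["ln_village_land"] = np.log1p(z["village_land"])
    return z


# ---------------------------------------------------------------------------
# generator


def generate_survey(
    design: SurveyDesign | None = None,
    effects: Mapping[str, EffectSpec] | None = None,
    calibration: Calibration | None = None,
    seed: int | None = None,
) -> SurveyData:
    """Generate a complete synthetic survey.

    All randomness flows from one generator seeded with ``seed`` (falling
    back to ``design.seed``); identical inputs give identical output.
    """
    design = design or SurveyDesign()
    cal = calibration or Calibration()
    effects = dict(effects) if effects is not None else dict(DEFAULT_EFFECTS)
    unknown = set(effects) - set(INDEX_NAMES)
    if unknown:
        raise ValueError(f"unknown outcome indices in effects: {sorted(unknown)}")
    if "CFPS" in effects:
        logger.warning(
            "a CFPS EffectSpec was supplied but the Pagoda score is emergent "
            "from the EI and CHEI dials; it will not be planted independently"
        )
    if "EI" not in effects or "CHEI" not in effects:
        raise ValueError("effects must include EffectSpecs for 'EI' and 'CHEI'")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_hh = design.n_households
    n_vil = design.n_villages
    n_cty = design.n_counties

    # --- identifiers (nested stratification) ---
    village_idx = np.repeat(np.arange(n_vil), design.households_per_village)
    vil_per_cty = design.townships_per_county * design.villages_per_township
    county_of_village = np.arange(n_vil) // vil_per_cty
    county_idx = county_of_village[village_idx]
    household_id = np.array([f"H{i + 1:05d}" for i in range(n_hh)])
    village_id = np.array([f"V{v + 1:04d}" for v in village_idx])
    county_id = np.array([f"C{c + 1:03d}" for c in county_idx])

    # --- village covariates ---
    v_pop = np.round(_lognormal(rng, cal.village_population_mean, cal.village_population_sd, n_vil))
    v_dist = _lognormal(rng, cal.village_distance_mean, cal.village_distance_sd, n_vil)
    v_market = np.round(_lognormal(rng, cal.food_market_density_mean, cal.food_market_density_sd, n_vil))
    v_income = _lognormal(rng, cal.village_income_mean, cal.village_income_sd, n_vil)
    v_land = _lognormal(rng, cal.village_land_mean, cal.village_land_sd, n_vil)

    # --- household covariates ---
    size = 1 + rng.poisson(cal.mean_household_size - 1.0, n_hh)
    ages, hh_of_member = _draw_ages(rng, size, cal)
    n_child = np.bincount(hh_of_member, weights=(ages < 18), minlength=n_hh)
    n_eld = np.bincount(hh_of_member, weights=(ages >= 65), minlength=n_hh)
    ratio_under18 = n_child / size * 100
    ratio_over65 = n_eld / size * 100
    ratio_18_65 = 100.0 - ratio_under18 - ratio_over65

    income = _lognormal(rng, cal.income_mean, cal.income_sd, n_hh)
    gender_dm = rng.binomial(1, cal.p_female_dm, n_hh)
    married_dm = rng.binomial(1, cal.p_married_dm, n_hh)
    education_dm = rng.binomial(1, cal.p_college_dm, n_hh)
    dki = rng.binomial(9, cal.dki_mean / 9.0, n_hh)
    has_pension = rng.binomial(1, cal.pension_p_positive, n_hh)
    pension = has_pension * _lognormal(
        rng, cal.pension_mean / cal.pension_p_positive, 0.8, n_hh
    )
    m, s = cal.off_farm_mean, cal.off_farm_sd
    conc = m * (1 - m) / s**2 - 1.0
    off_farm = rng.beta(max(m * conc, 0.05), max((1 - m) * conc, 0.05), n_hh)
    distance_km = _lognormal(rng, cal.distance_mean, cal.distance_sd, n_hh)
    land_ha = _lognormal(rng, cal.land_mean, cal.land_sd, n_hh)
    crop_diversity = rng.poisson(cal.crop_diversity_mean, n_hh)
    prop = _lognormal(rng, cal.property_mean, cal.property_sd, n_hh)

    covariates = pd.DataFrame(
        {
            "household_id": household_id,
            "village_id": village_id,
            "county_id": county_id,
            "ratio_under18": ratio_under18,
            "ratio_18_65": ratio_18_65,
            "ratio_over65": ratio_over65,
            "income": income,
            "gender_dm": gender_dm,
            "married_dm": married_dm,
            "education_dm": education_dm,
            "dki": dki,
            "pension": pension,
            "off_farm": off_farm,
            "distance_km": distance_km,
            "land_ha": land_ha,
            "crop_diversity": crop_diversity,
            "household_size": size,
            "property": prop,
            "village_population": v_pop[village_idx],
            "village_distance": v_dist[village_idx],
            "food_market_density": v_market[village_idx],
            "village_income": v_income[village_idx],
            "village_land": v_land[village_idx],
        }
    )
    regs = derive_regressors(covariates)

    # --- planted index targets ---
    def draw_target(spec: EffectSpec) -> np.ndarray:
        y = np.full(n_hh, spec.intercept)
        y += spec.beta_under18 * ratio_under18 + spec.beta_over65 * ratio_over65
        y += spec.gamma_income * income
        for name, beta in spec.control_betas.items():
            y += beta * regs[name].to_numpy(dtype=float)
        if spec.county_sd > 0:
            y += rng.normal(0.0, spec.county_sd, n_cty)[county_idx]
        y += rng.normal(0.0, spec.noise_sd, n_hh)
        return y

    ei_target = np.clip(draw_target(effects["EI"]), 0.02, LN12 - 0.02)
    chei_target = np.clip(draw_target(effects["CHEI"]), 0.5, 59.5)

    # --- consumption synthesis (shares dial + scale dial) ---
    w = shares_for_entropy(ei_target)
    w = rng.permuted(w, axis=1)  # no systematic favorite group
    comps = load_chei_components()
    R = np.array([comps[g].R for g in FoodGroup])
    T = scale_for_chei(w, chei_target, R)
    intake = T[:, None] * w  # g/person/day per group

    # --- meal ledger ---
    fam = rng.binomial(
        np.repeat(size * 3, design.days).reshape(n_hh, design.days),
        cal.p_meal_at_home,
    )
    guests = rng.poisson(cal.guest_meal_rate, (n_hh, design.days))
    dead = (fam.sum(axis=1) + guests.sum(axis=1)) == 0
    fam[dead, 0] = 1  # at least one at-home person-meal
    person_days = (fam.sum(axis=1) + guests.sum(axis=1)) / 3.0

    meals = pd.DataFrame(
        {
            "household_id": np.repeat(household_id, design.days),
            "day": np.tile(np.arange(1, design.days + 1), n_hh),
            "family_person_meals": fam.ravel(),
            "guest_person_meals": guests.ravel(),
        }
    )

    # --- consumption records: household totals split over days ---
    day_w = rng.gamma(5.0, 1.0, (n_hh, design.days))
    day_w /= day_w.sum(axis=1, keepdims=True)
    totals = intake * person_days[:, None]  # household total grams per group
    grams = totals[:, None, :] * day_w[:, :, None]  # (hh, day, group)
    consumption = pd.DataFrame(
        {
            "household_id": np.repeat(household_id, design.days * N_FOOD_GROUPS),
            "day": np.tile(np.repeat(np.arange(1, design.days + 1), N_FOOD_GROUPS), n_hh),
            "food_group": np.tile(FOOD_GROUP_NAMES, n_hh * design.days),
            "grams": grams.ravel(),
        }
    )
    consumption = consumption[consumption["grams"] > 0].reset_index(drop=True)

    true_index = pd.DataFrame(
        {"household_id": household_id, "EI_target": ei_target, "CHEI_target": chei_target}
    )
    return SurveyData(
        consumption=consumption,
        meals=meals,
        covariates=covariates,
        design=design,
        effects=effects,
        true_index=true_index,
    )


def null_effects(noise_sd_ei: float = 0.28, noise_sd_chei: float = 6.0) -> dict[str, EffectSpec]:
    """EffectSpecs with every focal and control effect zero (noise only)."""
    return {
        "EI": replace(DEFAULT_EFFECTS["EI"], beta_under18=0.0, beta_over65=0.0,
                      gamma_income=0.0, control_betas={}, county_sd=0.0,
                      noise_sd=noise_sd_ei),
        "CHEI": replace(DEFAULT_EFFECTS["CHEI"], beta_under18=0.0, beta_over65=0.0,
                        gamma_income=0.0, control_betas={}, county_sd=0.0,
                        noise_sd=noise_sd_chei),
    }
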
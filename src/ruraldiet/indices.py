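"""The three dietary-health indices.

* **Entropy Index (EI)** — Shannon entropy of edible-weight shares across the
  twelve food groups, in nats: ``EI = -sum_i w_i ln w_i`` with
  ``w_i = intake_i / total``.  0 means a single-group diet; ln 12 ~ 2.48 means
  perfectly even intake.
* **Chinese Food Pagoda Score (CFPS)** — per Pagoda category a three-tier
  score: 1 inside the recommended band [L, U], 0.5 outside the band but
  within 50% relative distance of either bound, 0 otherwise; summed over the
  eight categories (range 0-8, step 0.5).
* **Chinese Healthy Eating Index (CHEI, 0-60 equal-weight variant)** — twelve
  5-point components, adequacy components scored ``min(intake/R, 1) * 5`` and
  limitation components by a descending linear ramp between L and U.

Households with zero total intake have undefined indices and are excluded
with a reason code rather than scored zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .foods import (
    DEFAULT_GROUP_TO_CATEGORY,
    FOOD_GROUP_NAMES,
    PAGODA_CATEGORIES,
    CheiComponent,
    FoodGroup,
    PagodaBounds,
    PagodaCategory,
    load_chei_components,
    load_pagoda_bounds,
)
from .intake import IntakeUndefinedError, PerCapitaIntake, standardize_intake

logger = logging.getLogger(__name__)

LN12 = float(np.log(12.0))


def entropy_index(intake: PerCapitaIntake) -> float:
    """Shannon entropy (nats) of the 12 weight shares; 0*ln 0 taken as 0."""
    x = intake.as_array()
    total = x.sum()
    if total <= 0:
        raise IntakeUndefinedError(
            f"household {intake.household_id}: zero total intake, EI undefined"
        )
    w = x / total
    nz = w[w > 0]
    return float(-(nz * np.log(nz)).sum())


def pagoda_category_score(intake_j: float, bounds: tuple[float, float]) -> float:
    """Three-tier adherence score for one Pagoda category.

    Full credit inside [L, U]; half credit when outside the band but within
    50% relative distance of either bound; zero otherwise.  The full-credit
    band takes precedence where the clauses overlap.
    """
    lo, hi = bounds
    if not (0 < lo <= hi):
        raise ValueError(f"invalid bounds ({lo}, {hi})")
    if intake_j < 0:
        raise ValueError("intake must be non-negative")
    if lo <= intake_j <= hi:
        return 1.0
    if abs(intake_j - lo) <= 0.5 * lo or abs(intake_j - hi) <= 0.5 * hi:
        return 0.5
    return 0.0


def category_intakes(
    intake: PerCapitaIntake,
    mapping: Mapping[FoodGroup, PagodaCategory] = DEFAULT_GROUP_TO_CATEGORY,
) -> dict[PagodaCategory, float]:
    """Aggregate the 12 group intakes into the 8 Pagoda categories."""
    if set(mapping) != set(FoodGroup):
        raise ValueError("group-to-category mapping must cover all 12 food groups")
    out = {c: 0.0 for c in PAGODA_CATEGORIES}
    for grp, cat in mapping.items():
        out[cat] += intake.intakes[grp.value]
    return out


def cfps(
    intake: PerCapitaIntake,
    bounds: PagodaBounds | None = None,
    mapping: Mapping[FoodGroup, PagodaCategory] = DEFAULT_GROUP_TO_CATEGORY,
) -> float:
    """Chinese Food Pagoda Score: sum of the eight category scores."""
    if bounds is None:
        bounds = load_pagoda_bounds()
    cats = category_intakes(intake, mapping)
    return float(sum(pagoda_category_score(cats[c], bounds[c]) for c in PAGODA_CATEGORIES))


def chei_component(intake_k: float, comp: CheiComponent) -> float:
    """Score one 5-point component (adequacy reward or limitation ramp)."""
    if intake_k < 0:
        raise ValueError("intake must be non-negative")
    if comp.kind == "adequacy":
        return min(intake_k / comp.R, 1.0) * comp.weight
    # limitation: full credit at or below L, linear ramp to 0 at U
    if intake_k <= comp.L:
        return comp.weight
    if intake_k >= comp.U:
        return 0.0
    return (1.0 - (intake_k - comp.L) / (comp.U - comp.L)) * comp.weight


def chei(
    intake: PerCapitaIntake,
    components: Mapping[FoodGroup, CheiComponent] | None = None,
) -> float:
    """Chinese Healthy Eating Index: sum of the twelve component scores."""
    if components is None:
        components = load_chei_components()
    if set(components) != set(FoodGroup):
        raise ValueError("need exactly one component per food group")
    return float(
        sum(chei_component(intake.intakes[g.value], components[g]) for g in FoodGroup)
    )


# ---------------------------------------------------------------------------
# vectorized batch scoring


def _ei_matrix(x: np.ndarray) -> np.ndarray:
    totals = x.sum(axis=1, keepdims=True)
    w = np.divide(x, totals, out=np.zeros_like(x), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(w > 0, -w * np.log(w), 0.0)
    return terms.sum(axis=1)


def _cfps_matrix(
    x: np.ndarray,
    bounds: PagodaBounds,
    mapping: Mapping[FoodGroup, PagodaCategory],
) -> np.ndarray:
    agg = np.zeros((x.shape[0], len(PAGODA_CATEGORIES)))
    cat_index = {c: j for j, c in enumerate(PAGODA_CATEGORIES)}
    for i, g in enumerate(FoodGroup):
        agg[:, cat_index[mapping[g]]] += x[:, i]
    lo = np.array([bounds[c][0] for c in PAGODA_CATEGORIES])
    hi = np.array([bounds[c][1] for c in PAGODA_CATEGORIES])
    in_band = (agg >= lo) & (agg <= hi)
    near = (np.abs(agg - lo) <= 0.5 * lo) | (np.abs(agg - hi) <= 0.5 * hi)
    s = np.where(in_band, 1.0, np.where(near, 0.5, 0.0))
    return s.sum(axis=1)


def _chei_matrix(
    x: np.ndarray, components: Mapping[FoodGroup, CheiComponent]
) -> np.ndarray:
    score = np.zeros(x.shape[0])
    for i, g in enumerate(FoodGroup):
        comp = components[g]
        v = x[:, i]
        if comp.kind == "adequacy":
            score += np.minimum(v / comp.R, 1.0) * comp.weight
        else:
            ramp = (1.0 - (v - comp.L) / (comp.U - comp.L)) * comp.weight
            score += np.where(v <= comp.L, comp.weight, np.where(v >= comp.U, 0.0, ramp))
    return score


@dataclass
class ScoreResult:
    """Batch scoring output: one row per scoreable household, plus exclusions."""

    scores: pd.DataFrame  # household_id, EI, CFPS, CHEI
    intakes: pd.DataFrame  # household_id x 12 group columns (g/person/day)
    excluded: pd.DataFrame  # household_id, reason


def score_dataset(
    records: pd.DataFrame,
    ledgers: pd.DataFrame,
    bounds: PagodaBounds | None = None,
    components: Mapping[FoodGroup, CheiComponent] | None = None,
    mapping: Mapping[FoodGroup, PagodaCategory] = DEFAULT_GROUP_TO_CATEGORY,
    meals_per_day: int = 3,
) -> ScoreResult:
    """Score every household in a consumption-record / meal-ledger pair.

    Duplicate (household, day, group) rows are summed before scoring.
    Households with no defined denominator or zero total intake are reported
    in ``excluded`` with a reason code, never silently scored 0.
    """
    if bounds is None:
        bounds = load_pagoda_bounds()
    if components is None:
        components = load_chei_components()

    score_cols = ["household_id", "EI", "CFPS", "CHEI"]
    if records.empty:
        logger.warning("empty consumption records: no households scored")
        return ScoreResult(
            scores=pd.DataFrame(columns=score_cols),
            intakes=pd.DataFrame(columns=["household_id", *FOOD_GROUP_NAMES]),
            excluded=pd.DataFrame(columns=["household_id", "reason"]),
        )
    rec_ids = set(records["household_id"])
    led_ids = set(ledgers["household_id"])
    if not rec_ids <= led_ids:
        raise ValueError(
            f"households missing from meal ledger: {sorted(rec_ids - led_ids)[:5]}"
        )
    if (records["grams"] < 0).any():
        raise ValueError("negative grams in consumption records")

    person_meals = (
        ledgers.assign(pm=ledgers["family_person_meals"] + ledgers["guest_person_meals"])
        .groupby("household_id")["pm"]
        .sum()
    )
    totals = (
        records.groupby(["household_id", "food_group"])["grams"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=FOOD_GROUP_NAMES, fill_value=0.0)
    )
    totals = totals.reindex(sorted(rec_ids), fill_value=0.0)

    pm = person_meals.reindex(totals.index).to_numpy(dtype=float)
    excluded = []
    ok = pm > 0
    for hh in totals.index[~ok]:
        excluded.append((hh, "zero_person_meals"))

    person_days = np.where(ok, pm, np.nan) / meals_per_day
    x = totals.to_numpy(dtype=float) / person_days[:, None]
    pos = ok & (np.nansum(x, axis=1) > 0)
    for hh in totals.index[ok & ~pos]:
        excluded.append((hh, "zero_total_intake"))

    keep = totals.index[pos]
    xk = x[pos]
    scores = pd.DataFrame(
        {
            "household_id": keep,
            "EI": _ei_matrix(xk),
            "CFPS": _cfps_matrix(xk, bounds, mapping),
            "CHEI": _chei_matrix(xk, components),
        }
    ).reset_index(drop=True)
    intakes = pd.DataFrame(xk, columns=FOOD_GROUP_NAMES)
    intakes.insert(0, "household_id", list(keep))
    excl = pd.DataFrame(excluded, columns=["household_id", "reason"])
    if len(excl):
        logger.info("excluded %d households: %s", len(excl), excl["reason"].value_counts().to_dict())
    return ScoreResult(scores=scores, intakes=intakes, excluded=excl)


__all__ = [
    "LN12",
    "ScoreResult",
    "category_intakes",
    "cfps",
    "chei",
    "chei_component",
    "entropy_index",
    "pagoda_category_score",
    "score_dataset",
    "standardize_intake",
]
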
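"""Standardization of household food-consumption records to per-capita intakes.

Household food records give total edible weight eaten at home over the survey
window; the meal ledger counts how many person-meals (family and guests) were
actually eaten at home each day.  Dividing total grams by the ledger-implied
person-days corrects for meals eaten away from home and for guests, giving
comparable grams/person/day intakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foods import FOOD_GROUP_NAMES


class IntakeUndefinedError(ValueError):
    """Raised when a household's per-capita intake has no defined denominator."""


@dataclass
class PerCapitaIntake:
    """Standardized grams/person/day for one household across the 12 groups."""

    household_id: str
    intakes: dict[str, float] = field(default_factory=dict)
    person_days: float = 0.0

    def __post_init__(self) -> None:
        if self.person_days <= 0:
            raise IntakeUndefinedError(
                f"household {self.household_id}: person_days must be > 0"
            )
        full = {g: 0.0 for g in FOOD_GROUP_NAMES}
        for g, v in self.intakes.items():
            if g not in full:
                raise ValueError(f"unknown food group {g!r}")
            if v < 0:
                raise ValueError(f"household {self.household_id}: negative intake for {g}")
            full[g] = float(v)
        self.intakes = full

    @property
    def total(self) -> float:
        return float(sum(self.intakes.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.intakes[g] for g in FOOD_GROUP_NAMES], dtype=float)


def standardize_intake(
    records: pd.DataFrame,
    ledger: pd.DataFrame,
    meals_per_day: int = 3,
) -> PerCapitaIntake:
    """Convert one household's raw records + meal ledger to per-capita intake.

    Parameters
    ----------
    records
        Columns ``household_id, day, food_group, grams`` for a single household.
    ledger
        Columns ``household_id, day, family_person_meals, guest_person_meals``
        for the same household.
    meals_per_day
        Meals in a full at-home day (default 3); person_days = total
        person-meals / meals_per_day.
    """
    if ledger.empty:
        raise IntakeUndefinedError("meal ledger is empty")
    hh_ids = set(ledger["household_id"].unique())
    if not records.empty:
        hh_ids |= set(records["household_id"].unique())
    if len(hh_ids) != 1:
        raise ValueError(f"expected a single household, got ids {sorted(hh_ids)}")
    (hh,) = hh_ids

    person_meals = float(
        ledger["family_person_meals"].sum() + ledger["guest_person_meals"].sum()
    )
    if person_meals <= 0:
        raise IntakeUndefinedError(f"household {hh}: zero total person-meals")
    person_days = person_meals / meals_per_day

    if (records["grams"] < 0).any():
        raise ValueError(f"household {hh}: negative grams in records")
    # duplicate (day, group) rows are summed before standardization
    totals = records.groupby("food_group")["grams"].sum()
    intakes = {g: float(totals.get(g, 0.0)) / person_days for g in FOOD_GROUP_NAMES}
    return PerCapitaIntake(household_id=str(hh), intakes=intakes, person_days=person_days)
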
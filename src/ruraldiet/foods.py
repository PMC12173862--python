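"""Food-group taxonomy and dietary-guideline tables.

Twelve primary food groups (sugar, sweets and soft drinks deliberately
excluded) underlie all three dietary-health indices.  For guideline-adherence
scoring the twelve groups are aggregated into the eight core categories of
the 2016 Chinese Dietary Pagoda; for the healthy-eating index each of the
twelve groups carries its own 5-point component.

The numeric bounds shipped in ``data/`` are seeded from the 2016 Pagoda
recommended daily ranges and are fully replaceable: every scoring rule
depends only on the table *structure* (a lower/upper band per category, an
adequacy target or limitation ramp per component), never on the specific
gram values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd


class FoodGroup(enum.Enum):
    """The twelve primary food groups, in canonical order."""

    CEREALS = "cereals"
    TUBERS = "tubers"
    DRIED_LEGUMES = "dried_legumes"
    VEGETABLES = "vegetables"
    FUNGI_ALGAE = "fungi_algae"
    FRUITS = "fruits"
    NUTS_SEEDS = "nuts_seeds"
    MEAT = "meat"
    POULTRY = "poultry"
    DAIRY = "dairy"
    EGGS = "eggs"
    AQUATIC = "aquatic"


FOOD_GROUPS: tuple[FoodGroup, ...] = tuple(FoodGroup)
FOOD_GROUP_NAMES: tuple[str, ...] = tuple(g.value for g in FoodGroup)
N_FOOD_GROUPS = len(FOOD_GROUPS)


class PagodaCategory(enum.Enum):
    """The eight core categories of the Chinese Dietary Pagoda."""

    GRAINS_TUBERS_LEGUMES = "grains_tubers_legumes"
    VEGETABLES = "vegetables"
    FRUITS = "fruits"
    MEAT_POULTRY = "meat_poultry"
    EGGS = "eggs"
    AQUATIC = "aquatic"
    DAIRY = "dairy"
    NUTS_SEEDS = "nuts_seeds"


PAGODA_CATEGORIES: tuple[PagodaCategory, ...] = tuple(PagodaCategory)

#: Default 12 -> 8 aggregation.  Cereals, tubers and dried legumes merge into
#: the grains tier; fungi/algae count as vegetables; meat and poultry merge.
DEFAULT_GROUP_TO_CATEGORY: Mapping[FoodGroup, PagodaCategory] = {
    FoodGroup.CEREALS: PagodaCategory.GRAINS_TUBERS_LEGUMES,
    FoodGroup.TUBERS: PagodaCategory.GRAINS_TUBERS_LEGUMES,
    FoodGroup.DRIED_LEGUMES: PagodaCategory.GRAINS_TUBERS_LEGUMES,
    FoodGroup.VEGETABLES: PagodaCategory.VEGETABLES,
    FoodGroup.FUNGI_ALGAE: PagodaCategory.VEGETABLES,
    FoodGroup.FRUITS: PagodaCategory.FRUITS,
    FoodGroup.NUTS_SEEDS: PagodaCategory.NUTS_SEEDS,
    FoodGroup.MEAT: PagodaCategory.MEAT_POULTRY,
    FoodGroup.POULTRY: PagodaCategory.MEAT_POULTRY,
    FoodGroup.DAIRY: PagodaCategory.DAIRY,
    FoodGroup.EGGS: PagodaCategory.EGGS,
    FoodGroup.AQUATIC: PagodaCategory.AQUATIC,
}


@dataclass(frozen=True)
class PagodaBounds:
    """Lower/upper recommended daily intake (g/person/day) per category."""

    bounds: Mapping[PagodaCategory, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = set(PAGODA_CATEGORIES) - set(self.bounds)
        if missing:
            raise ValueError(f"missing Pagoda bounds for: {sorted(c.value for c in missing)}")
        for cat, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid bounds for {cat.value}: need 0 < L <= U, got ({lo}, {hi})")

    def __getitem__(self, cat: PagodaCategory) -> tuple[float, float]:
        return self.bounds[cat]


@dataclass(frozen=True)
class CheiComponent:
    """One 5-point component of the healthy-eating index.

    Adequacy components (encouraged foods) reward intake up to a recommended
    level ``R``; limitation components (foods to curb) score full credit at or
    below the ideal limit ``L`` and ramp linearly down to zero at the cut-off
    ``U``.
    """

    group: FoodGroup
    kind: str  # "adequacy" | "limitation"
    R: float | None = None
    L: float | None = None
    U: float | None = None
    weight: float = 5.0

    def __post_init__(self) -> None:
        if self.kind == "adequacy":
            if self.R is None or self.R <= 0:
                raise ValueError(f"{self.group.value}: adequacy component needs R > 0")
        elif self.kind == "limitation":
            if self.L is None or self.U is None or not (0 <= self.L < self.U):
                raise ValueError(f"{self.group.value}: limitation component needs 0 <= L < U")
        else:
            raise ValueError(f"unknown component kind {self.kind!r}")


def _data_path(name: str):
    return resources.files("ruraldiet.data").joinpath(name)


def load_pagoda_bounds(path=None) -> PagodaBounds:
    """Read an 8-row ``category,L,U`` CSV; defaults to the packaged table."""
    src = path if path is not None else _data_path("pagoda_bounds.csv")
    df = pd.read_csv(src)
    bounds = {
        PagodaCategory(row.category): (float(row.L), float(row.U))
        for row in df.itertuples(index=False)
    }
    return PagodaBounds(bounds)


def load_chei_components(path=None) -> dict[FoodGroup, CheiComponent]:
    """Read a 12-row ``component,kind,R,L,U`` CSV; defaults to the packaged table."""
    src = path if path is not None else _data_path("chei_components.csv")
    df = pd.read_csv(src)
    comps: dict[FoodGroup, CheiComponent] = {}
    for row in df.itertuples(index=False):
        grp = FoodGroup(row.component)
        comps[grp] = CheiComponent(
            group=grp,
            kind=row.kind,
            R=None if pd.isna(row.R) else float(row.R),
            L=None if pd.isna(row.L) else float(row.L),
            U=None if pd.isna(row.U) else float(row.U),
        )
    if len(comps) != N_FOOD_GROUPS:
        raise ValueError(f"expected {N_FOOD_GROUPS} components, got {len(comps)}")
    return comps
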
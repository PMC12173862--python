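import numpy as np
import pandas as pd
import pytest

from ruraldiet import (
    Calibration,
    PerCapitaIntake,
    SurveyDesign,
    generate_survey,
    load_chei_components,
    load_pagoda_bounds,
    score_dataset,
)


@pytest.fixture(scope="session")
def pagoda_bounds():
    return load_pagoda_bounds()


@pytest.fixture(scope="session")
def chei_components():
    return load_chei_components()


@pytest.fixture(scope="session")
def small_design():
    """1 province x 2 x 2 x 2 x 5 = 40 households; fast for unit tests."""
    return SurveyDesign(
        provinces=1, counties_per_province=2, townships_per_county=2,
        villages_per_township=2, households_per_village=5,
    )


@pytest.fixture(scope="session")
def small_survey(small_design):
    return generate_survey(small_design, seed=7)


@pytest.fixture(scope="session")
def default_survey():
    """The full study design: 1,080 households in 108 villages."""
    return generate_survey(seed=11)


@pytest.fixture(scope="session")
def default_scored(default_survey):
    res = score_dataset(default_survey.consumption, default_survey.meals)
    return res.scores.merge(default_survey.covariates, on="household_id")


def uniform_intake(grams: float = 120.0) -> PerCapitaIntake:
    from ruraldiet import FOOD_GROUP_NAMES

    return PerCapitaIntake(
        household_id="H1",
        intakes={g: grams for g in FOOD_GROUP_NAMES},
        person_days=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
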
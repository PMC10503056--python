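import numpy as np
import pandas as pd
import pytest

from cvdscreen import (
    ParameterSet,
    PopulationSpec,
    attach_event_probabilities,
    generate_population,
)
from cvdscreen.parameters import LifeTable
from cvdscreen.risk import CaseFatalityTable


@pytest.fixture(scope="session")
def pop500():
    return generate_population(PopulationSpec(n=500, seed=42))


@pytest.fixture(scope="session")
def pop2000():
    return generate_population(PopulationSpec(n=2000, seed=7))


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


def make_person(**overrides) -> pd.DataFrame:
    """One-row population frame with benign defaults."""
    row = {
        "person_id": 0,
        "age": 55.0,
        "sex": "female",
        "sbp": 120.0,
        "dbp": 75.0,
        "total_cholesterol": 190.0,
        "fasting_glucose": 95.0,
        "random_glucose": 110.0,
        "diabetes": False,
        "smoker": False,
        "bmi": 24.0,
        "baseline_utility": 0.9,
        "survey_weight": 1.0,
        "prior_cvd": False,
    }
    row.update(overrides)
    return pd.DataFrame([row])


def flat_case_fatality(fraction: float, age_lo: int = 30, age_hi: int = 100):
    rows = [
        {"condition": c, "sex": s, "age_lo": lo, "fraction": fraction}
        for c in ("chd", "stroke")
        for s in ("female", "male")
        for lo in range(age_lo, age_hi, 5)
    ]
    return CaseFatalityTable(pd.DataFrame(rows))


def simple_params(**overrides) -> ParameterSet:
    """Parameters stripped to the bone: no background mortality or usual
    care unless the test opts in."""
    defaults = dict(
        life_table=LifeTable.flat(0.0),
        case_fatality=flat_case_fatality(0.3),
        usual_care_inpatient=0.0,
        usual_care_outpatient=0.0,
        disutility_age_per_year=0.0,
    )
    defaults.update(overrides)
    return ParameterSet(**defaults)


@pytest.fixture(scope="session")
def screened_pop500(pop500):
    return attach_event_probabilities(pop500)


def rng(seed=0):
    return np.random.default_rng(seed)
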
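"""Model parameters: costs, treatment effects, disutilities, mortality.

:class:`ParameterSet` collects every quantity the lifetime Markov model
needs — annual medication and test costs (December-2019 USD), relative
risks of statins and antihypertensives on fatal/non-fatal events,
post-event annual death probabilities, usual-care cost inflation ratios,
utility decrements, the discount rate and the treatment-effect horizon —
alongside an age/sex life table and a case-fatality table.

Defaults are the study's point estimates where the source prints them;
the life table, case-fatality fractions and base per-capita usual-care
costs are synthetic stand-ins (the originals are not published at this
granularity) and are clearly labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
import yaml

from .risk import CaseFatalityTable, RiskModelError


class LifeTable:
    """Annual probability of death by sex and single year of age."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age", "q"}
        if not required.issubset(table.columns):
            raise RiskModelError(f"life table needs columns {sorted(required)}")
        if ((table["q"] < 0) | (table["q"] > 1)).any():
            raise RiskModelError("life-table probabilities must lie in [0, 1]")
        self._q: dict[str, np.ndarray] = {}
        self._lo: dict[str, int] = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy(dtype=int)
            if not np.all(np.diff(ages) == 1):
                raise RiskModelError(f"life table ages for {sex} must be contiguous")
            self._q[str(sex)] = grp["q"].to_numpy(dtype=float)
            self._lo[str(sex)] = int(ages[0])

    def q(self, sex, age) -> np.ndarray:
        """Annual death probability; ages beyond the table clamp to its last row."""
        sex = np.atleast_1d(np.asarray(sex))
        age = np.atleast_1d(np.asarray(age))
        sex, age = np.broadcast_arrays(sex, age)
        out = np.empty(age.shape, dtype=float)
        for s in np.unique(sex):
            key = str(s)
            if key not in self._q:
                raise RiskModelError(f"life table does not cover sex {key!r}")
            idx = np.asarray(age[sex == s], dtype=int) - self._lo[key]
            if np.any(idx < 0):
                raise RiskModelError(f"life table for {key} does not cover requested ages")
            out[sex == s] = self._q[key][np.clip(idx, 0, len(self._q[key]) - 1)]
        return out

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    @classmethod
    def flat(cls, q: float, sexes=("female", "male"), ages=range(0, 121)) -> "LifeTable":
        """Constant-hazard table, mainly for tests and worked examples."""
        rows = [{"sex": s, "age": a, "q": q} for s in sexes for a in ages]
        return cls(pd.DataFrame(rows))


def _packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("cvdscreen.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text))


def default_life_table() -> LifeTable:
    """Packaged synthetic Gompertz–Makeham life table."""
    return LifeTable(_packaged_csv("life_table_synthetic.csv"))


def default_case_fatality() -> CaseFatalityTable:
    """Packaged synthetic age-increasing case-fatality fractions."""
    return CaseFatalityTable(_packaged_csv("case_fatality_synthetic.csv"))


@dataclass(frozen=True)
class ParameterSet:
    """All tunable model quantities (costs in December-2019 USD)."""

    # annual probability of death after a non-fatal event, while the
    # post-event excess-mortality window (first 10 cycles) is open
    p_death_post_chd: float = 0.03
    p_death_post_stroke: float = 0.10

    # relative risks of treatment on annual event probabilities
    rr_statin_nonfatal_chd: float = 0.74
    rr_statin_nonfatal_stroke: float = 0.86
    rr_statin_fatal_chd: float = 0.82
    rr_statin_fatal_stroke: float = 0.92
    rr_antihyp_nonfatal_chd: float = 0.86
    rr_antihyp_nonfatal_stroke: float = 0.86
    rr_antihyp_fatal_chd: float = 0.86
    rr_antihyp_fatal_stroke: float = 0.86

    # annual medication costs
    cost_statin: float = 3.98            # atorvastatin 20 mg/day
    cost_enalapril: float = 2.21         # enalapril 5 mg/day
    cost_nifedipine: float = 0.78        # nifedipine SR 20 mg/day
    cost_metformin: float = 6.27         # metformin 500 mg tid

    # test and visit costs
    cost_glucose_test: float = 0.17
    cost_cholesterol_test: float = 0.19
    cost_consultation: float = 1.96

    # event admission costs
    cost_mi_admission: float = 318.0
    cost_stroke_admission: float = 241.0

    # usual-care: base per-capita annual costs (synthetic stand-ins) and
    # state-specific inflation ratios
    usual_care_inpatient: float = 18.0
    usual_care_outpatient: float = 22.0
    inflation_general: float = 1.00
    inflation_inpatient_chd: float = 2.85
    inflation_inpatient_stroke: float = 1.09
    inflation_outpatient_chd: float = 1.95
    inflation_outpatient_stroke: float = 1.97

    # utilities
    disutility_nonfatal_chd: float = -0.0210
    disutility_nonfatal_stroke: float = -0.2493
    disutility_age_per_year: float = -0.0066
    pill_disutility: float = 0.0         # sensitivity value 0.00384
    utility_floor: float = -1.0

    # horizons and discounting
    discount_rate: float = 0.03
    effect_horizon: int = 10             # cycles with treatment effect + events
    max_age: int = 100
    case_fatality_multiplier: float = 1.0

    # mortality tables (not varied through dataclass replace in PSA draws
    # except via the case-fatality multiplier)
    life_table: LifeTable = field(default_factory=default_life_table, compare=False)
    case_fatality: CaseFatalityTable = field(
        default_factory=default_case_fatality, compare=False
    )

    def __post_init__(self):
        for name in ("p_death_post_chd", "p_death_post_stroke", "discount_rate"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name, v in self.scalar_dict().items():
            if name.startswith("rr_") and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            if name.startswith("cost_") and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def scalar_dict(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("life_table"), d.pop("case_fatality")
        return d

    def with_(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    @property
    def cost_antihypertensive(self) -> float:
        """Annual antihypertensive regimen cost (both listed drugs)."""
        return self.cost_enalapril + self.cost_nifedipine

    def effective_case_fatality(self) -> CaseFatalityTable:
        if self.case_fatality_multiplier == 1.0:
            return self.case_fatality
        return self.case_fatality.scaled(self.case_fatality_multiplier)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        """Load scalar overrides from a YAML mapping of field names."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls().scalar_dict())
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**doc)
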
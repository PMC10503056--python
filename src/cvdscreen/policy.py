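"""Screening-program designs and treatment-assignment rules.

A :class:`ScenarioSpec` pins down one program design: which risk tool is
used (office or lab version), who is eligible by age, what 10-year CVD
risk counts as "high risk", and two optional policy extensions —
prescribing statins to all diabetics, and lowering the blood-pressure
treatment threshold to 130/80 for diabetics and high-risk persons.

Treatment rules applied to every screened person:

* antihypertensives at BP >= 140/90 (sbp OR dbp criterion); with the
  lowered-threshold policy, also at >= 130/80 for diabetics / high-risks;
* hypoglycaemics at fasting glucose >= 126 mg/dL or random >= 200 mg/dL;
* statins for high CVD risk, for total cholesterol >= 300 mg/dL in lab
  scenarios, and for all diabetics when that policy is on.

Follow-up: high-risk persons get two visits and two glucose tests per
year (plus a cholesterol test per visit in lab scenarios); medicated
non-high-risk persons get one visit and glucose test per year, with one
extra visit in the initial year.  Medication, once started, continues
for life.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import risk as riskmod

logger = logging.getLogger(__name__)

#: One year's screening throughput: 20 patients/week in 1,000 clinics for
#: 48 weeks, running at 70% capacity.
DEFAULT_CAPACITY = int(20 * 1_000 * 48 * 0.70)

SBP_TREAT, DBP_TREAT = 140.0, 90.0
SBP_TREAT_LOW, DBP_TREAT_LOW = 130.0, 80.0
CHOLESTEROL_TREAT = 300.0
FASTING_GLUCOSE_TREAT = 126.0
RANDOM_GLUCOSE_TREAT = 200.0

PLAN_COLUMNS = [
    "high_risk", "antihypertensive", "statin", "hypoglycaemic", "newly_started_any",
    "follow_ups_initial_year", "follow_ups_subsequent_years",
    "glucose_tests_per_year", "cholesterol_tests_per_year",
]


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One screening-program design."""

    scenario_id: str
    risk_tool: str = "who_ish"
    mode: str = "office"
    age_rule: str = "35plus"
    high_risk_threshold: float = 0.20
    statins_all_diabetics: bool = False
    lowered_bp_threshold: bool = False
    capacity: int = DEFAULT_CAPACITY

    def __post_init__(self):
        if not 0.0 < self.high_risk_threshold < 1.0:
            raise ScenarioError(
                f"high_risk_threshold must be in (0,1), got {self.high_risk_threshold}"
            )
        if self.capacity <= 0:
            raise ScenarioError(f"capacity must be positive, got {self.capacity}")
        if self.age_rule not in ("35plus", "40plus", "40to65"):
            raise ScenarioError(f"unknown age_rule {self.age_rule!r}")
        if self.mode not in ("office", "lab"):
            raise ScenarioError(f"mode must be office or lab, got {self.mode!r}")

    def with_(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


def base_case(capacity: int = DEFAULT_CAPACITY) -> ScenarioSpec:
    """The current protocol: WHO-ISH office chart, 20% threshold, 35+."""
    return ScenarioSpec("base", "who_ish", "office", "35plus", 0.20, False, False, capacity)


def build_scenario_grid(
    tools: list[tuple[str, str]] | None = None,
    age_rules: tuple[str, ...] = ("35plus", "40plus"),
    thresholds: tuple[float, ...] = (0.20, 0.10),
    statins_all_diabetics: tuple[bool, ...] = (False, True),
    lowered_bp_threshold: tuple[bool, ...] = (False, True),
    capacity: int = DEFAULT_CAPACITY,
) -> list[ScenarioSpec]:
    """Cartesian product of the design axes, plus the distinguished base case.

    The default axes (8 tool/mode pairs x 2 age rules x 2 thresholds x
    2 x 2 policy flags) give 128 alternatives + 1 base = 129 scenarios.
    """
    if tools is None:
        tools = riskmod.available_tools()
    for name, axis in (
        ("tools", tools), ("age_rules", age_rules), ("thresholds", thresholds),
        ("statins_all_diabetics", statins_all_diabetics),
        ("lowered_bp_threshold", lowered_bp_threshold),
    ):
        if len(set(axis)) != len(axis):
            raise ScenarioError(f"duplicate values in axis {name!r}")
    scenarios = [base_case(capacity)]
    for (tool, mode), age_rule, thr, sd, lbp in itertools.product(
        tools, age_rules, thresholds, statins_all_diabetics, lowered_bp_threshold
    ):
        sid = (
            f"{tool}-{mode}_{age_rule}_t{int(round(thr * 100)):02d}"
            f"_SD{int(sd)}_LBP{int(lbp)}"
        )
        scenarios.append(
            ScenarioSpec(sid, tool, mode, age_rule, thr, sd, lbp, capacity)
        )
    ids = [s.scenario_id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ScenarioError("scenario ids are not unique")
    return scenarios


def eligible(age, prior_cvd, scenario: ScenarioSpec) -> np.ndarray:
    """Screening eligibility: the age rule, and no previous CVD."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    prior = np.atleast_1d(np.asarray(prior_cvd, dtype=bool))
    if scenario.age_rule == "35plus":
        ok = age >= 35
    elif scenario.age_rule == "40plus":
        ok = age >= 40
    else:  # 40to65
        ok = (age >= 40) & (age <= 65)
    return ok & ~prior


def assign_treatments(
    data: pd.DataFrame, scenario: ScenarioSpec, p10_combined: np.ndarray
) -> pd.DataFrame:
    """Vectorised treatment assignment for screened persons.

    Returns a DataFrame of :data:`PLAN_COLUMNS` aligned to ``data``.
    """
    sbp = data["sbp"].to_numpy(dtype=float)
    dbp = data["dbp"].to_numpy(dtype=float)
    diab = data["diabetes"].to_numpy(dtype=bool)

    high_risk = np.asarray(p10_combined, dtype=float) >= scenario.high_risk_threshold

    antihyp = (sbp >= SBP_TREAT) | (dbp >= DBP_TREAT)
    if scenario.lowered_bp_threshold:
        antihyp |= (diab | high_risk) & ((sbp >= SBP_TREAT_LOW) | (dbp >= DBP_TREAT_LOW))

    statin = high_risk.copy()
    if scenario.mode == "lab":
        statin |= data["total_cholesterol"].to_numpy(dtype=float) >= CHOLESTEROL_TREAT
    if scenario.statins_all_diabetics:
        statin |= diab

    hypogly = (data["fasting_glucose"].to_numpy(dtype=float) >= FASTING_GLUCOSE_TREAT) | (
        data["random_glucose"].to_numpy(dtype=float) >= RANDOM_GLUCOSE_TREAT
    )

    plan = pd.DataFrame(
        {
            "high_risk": high_risk,
            "antihypertensive": antihyp,
            "statin": statin,
            "hypoglycaemic": hypogly,
            "newly_started_any": antihyp | statin | hypogly,
        },
        index=data.index,
    )
    return follow_up_schedule(plan, scenario)


def follow_up_schedule(plan: pd.DataFrame, scenario: ScenarioSpec) -> pd.DataFrame:
    """Attach follow-up visit and test counts to a treatment plan."""
    plan = plan.copy()
    high = plan["high_risk"].to_numpy(dtype=bool)
    medicated = plan["newly_started_any"].to_numpy(dtype=bool)
    med_not_high = medicated & ~high

    plan["follow_ups_initial_year"] = np.select([high, med_not_high], [2, 2], default=0)
    plan["follow_ups_subsequent_years"] = np.select([high, med_not_high], [2, 1], default=0)
    plan["glucose_tests_per_year"] = np.select([high, med_not_high], [2, 1], default=0)
    plan["cholesterol_tests_per_year"] = (
        2 * (high.astype(int)) if scenario.mode == "lab" else np.zeros(len(plan), dtype=int)
    )
    return plan[PLAN_COLUMNS]


def screen_cohort(population: pd.DataFrame, scenario: ScenarioSpec, tool=None):
    """Apply a scenario to a population.

    Returns ``(screened, plan, summary)`` where ``screened`` is the
    eligible subset of ``population``, ``plan`` the aligned treatment
    plan, and ``summary`` a dict of survey-weighted percentages of
    screened persons newly commenced on each medication class.
    """
    if tool is None:
        tool = riskmod.load_tool(scenario.risk_tool, scenario.mode)
    mask = eligible(population["age"], population["prior_cvd"], scenario)
    screened = population.loc[mask].copy()
    if screened.empty:
        logger.warning("scenario %s: no eligible persons", scenario.scenario_id)
        zero = {k: 0.0 for k in
                ("pct_antihypertensive", "pct_statin", "pct_hypoglycaemic", "pct_any")}
        return screened, pd.DataFrame(columns=PLAN_COLUMNS), zero

    p10 = tool.combined_risk(screened)
    screened["p10_classification"] = p10
    plan = assign_treatments(screened, scenario, p10)

    w = screened["survey_weight"].to_numpy(dtype=float)
    wtot = w.sum()
    if wtot <= 0:
        raise ScenarioError("total survey weight of screened persons is zero")

    def pct(col):
        return 100.0 * float(w[plan[col].to_numpy(dtype=bool)].sum()) / wtot

    summary = {
        "pct_antihypertensive": pct("antihypertensive"),
        "pct_statin": pct("statin"),
        "pct_hypoglycaemic": pct("hypoglycaemic"),
        "pct_any": pct("newly_started_any"),
    }
    return screened, plan, summary
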
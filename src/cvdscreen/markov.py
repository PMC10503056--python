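"""Lifetime five-state Markov model with expected-value propagation.

Each screened person is propagated as a state-occupancy distribution over
``{NO_CVD, POST_CHD, POST_STROKE, DEAD_CVD, DEAD_OTHER}`` with 1-year
cycles.  During the first ``effect_horizon`` (default 10) cycles the
person faces annual CHD and stroke event probabilities (split into fatal
and non-fatal parts by an age/sex case-fatality table, reduced by the
relative risks of any medication taken) plus natural mortality applied
to the event-free remainder; the post-event states face the elevated
post-event death probabilities, floored at natural mortality.  After the
horizon, all alive states face natural mortality only — treatment
continues (and is paid for) for life but confers no further risk
reduction.  Cycles run until certain death or age ``max_age``.

QALY and recurring cost flows are half-cycle corrected (valued at the
average of start- and end-of-cycle occupancy) and discounted at
``1/(1+r)**cycle``.  One-off flows — the year-0 screening visit and
event admission costs — are not half-cycle corrected.

The propagation is deterministic (no first-order Monte-Carlo noise);
parameter uncertainty is carried by the probabilistic sensitivity
analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from . import risk as riskmod
from .parameters import ParameterSet
from .policy import PLAN_COLUMNS, ScenarioSpec


class HealthState(IntEnum):
    NO_CVD = 0
    POST_CHD = 1
    POST_STROKE = 2
    DEAD_CVD = 3
    DEAD_OTHER = 4


N_STATES = len(HealthState)
ALIVE = (HealthState.NO_CVD, HealthState.POST_CHD, HealthState.POST_STROKE)

OUTCOME_COLUMNS = [
    "discounted_qalys", "discounted_costs", "undiscounted_qalys", "undiscounted_costs",
    "life_years", "chd_nonfatal", "chd_fatal", "stroke_nonfatal", "stroke_fatal",
]


@dataclass(frozen=True)
class LifetimeOutcome:
    """Per-person lifetime totals from the Markov propagation."""

    discounted_qalys: float
    discounted_costs: float
    undiscounted_qalys: float
    undiscounted_costs: float
    life_years: float
    chd_nonfatal: float
    chd_fatal: float
    stroke_nonfatal: float
    stroke_fatal: float


def attach_event_probabilities(
    population: pd.DataFrame, tool=None, params: ParameterSet | None = None
) -> pd.DataFrame:
    """Add ground-truth annual event probabilities ``p1_chd``/``p1_stroke``.

    Event simulation always uses the laboratory WHO-2019-style equation
    pair (the classification tool of a scenario only decides who counts
    as high risk); the 10-year risks are converted to annual ones with
    the constant-hazard identity.
    """
    if tool is None:
        tool = riskmod.load_tool("who2019", "lab")
    horizon = params.effect_horizon if params is not None else 10
    out = population.copy()
    out["p1_chd"] = riskmod.annualize_probability(tool.risk(population, "chd"), horizon)
    out["p1_stroke"] = riskmod.annualize_probability(tool.risk(population, "stroke"), horizon)
    return out


def apply_treatment_effects(
    p_fatal, p_nonfatal, condition: str, statin, antihypertensive,
    params: ParameterSet, cycle_index: int,
):
    """Multiply event probabilities by the RRs of the medications taken.

    Statin and antihypertensive effects compose multiplicatively; beyond
    ``params.effect_horizon`` cycles the probabilities are returned
    unmodified (treatment confers no further risk reduction).
    """
    if cycle_index > params.effect_horizon:
        return p_fatal, p_nonfatal
    statin = np.asarray(statin, dtype=bool)
    antihyp = np.asarray(antihypertensive, dtype=bool)
    if condition == "chd":
        rr_f = np.where(statin, params.rr_statin_fatal_chd, 1.0) * np.where(
            antihyp, params.rr_antihyp_fatal_chd, 1.0
        )
        rr_nf = np.where(statin, params.rr_statin_nonfatal_chd, 1.0) * np.where(
            antihyp, params.rr_antihyp_nonfatal_chd, 1.0
        )
    elif condition == "stroke":
        rr_f = np.where(statin, params.rr_statin_fatal_stroke, 1.0) * np.where(
            antihyp, params.rr_antihyp_fatal_stroke, 1.0
        )
        rr_nf = np.where(statin, params.rr_statin_nonfatal_stroke, 1.0) * np.where(
            antihyp, params.rr_antihyp_nonfatal_stroke, 1.0
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return np.clip(p_fatal * rr_f, 0.0, 1.0), np.clip(p_nonfatal * rr_nf, 0.0, 1.0)


def utility_flow(baseline_utility, state: int, years_since_baseline, newly_started_any,
                 params: ParameterSet):
    """Annual utility in an alive state.

    baseline utility, minus the per-year ageing decrement, plus the state
    decrement (post-CHD / post-stroke), minus the pill disutility for
    persons newly started on any medication; floored at
    ``params.utility_floor`` and capped at 1.
    """
    u = (
        np.asarray(baseline_utility, dtype=float)
        + params.disutility_age_per_year * np.asarray(years_since_baseline, dtype=float)
        - params.pill_disutility * np.asarray(newly_started_any, dtype=float)
    )
    if state == HealthState.POST_CHD:
        u = u + params.disutility_nonfatal_chd
    elif state == HealthState.POST_STROKE:
        u = u + params.disutility_nonfatal_stroke
    elif state != HealthState.NO_CVD:
        raise ValueError("utility defined only for alive states")
    return np.clip(u, params.utility_floor, 1.0)


def screening_cost(scenario: ScenarioSpec, params: ParameterSet) -> float:
    """Year-0 screening visit: consultation + glucose test (+ cholesterol in lab)."""
    cost = params.cost_consultation + params.cost_glucose_test
    if scenario.mode == "lab":
        cost += params.cost_cholesterol_test
    return cost


def _usual_care_costs(params: ParameterSet) -> np.ndarray:
    """Annual usual-care cost by alive state."""
    inp, outp = params.usual_care_inpatient, params.usual_care_outpatient
    return np.array([
        (inp + outp) * params.inflation_general,
        inp * params.inflation_inpatient_chd + outp * params.inflation_outpatient_chd,
        inp * params.inflation_inpatient_stroke + outp * params.inflation_outpatient_stroke,
    ])


def cost_flow(state: int, cycle_index: int, plan_row, params: ParameterSet) -> float:
    """Annual recurring cost for one person fully occupying ``state``.

    Covers medication, follow-up visits/tests and usual care; one-off
    event admission and screening costs are handled separately.
    """
    if state in (HealthState.DEAD_CVD, HealthState.DEAD_OTHER):
        return 0.0
    med = (
        params.cost_statin * bool(plan_row["statin"])
        + params.cost_antihypertensive * bool(plan_row["antihypertensive"])
        + params.cost_metformin * bool(plan_row["hypoglycaemic"])
    )
    visits = (
        plan_row["follow_ups_initial_year"]
        if cycle_index == 1
        else plan_row["follow_ups_subsequent_years"]
    )
    follow = (
        visits * params.cost_consultation
        + plan_row["glucose_tests_per_year"] * params.cost_glucose_test
        + plan_row["cholesterol_tests_per_year"] * params.cost_cholesterol_test
    )
    usual = _usual_care_costs(params)[int(state)]
    return float(med + follow + usual)


def transition_matrix(
    sex: str, age: int, p1_chd: float, p1_stroke: float, plan_row,
    params: ParameterSet, cycle_index: int,
) -> np.ndarray:
    """Single-person transition matrix for one cycle (rows sum to 1)."""
    probs = _cycle_probabilities(
        np.asarray([sex]), np.asarray([age]),
        np.asarray([p1_chd]), np.asarray([p1_stroke]),
        np.asarray([bool(plan_row["statin"])]),
        np.asarray([bool(plan_row["antihypertensive"])]),
        params, cycle_index,
    )
    m = np.zeros((N_STATES, N_STATES))
    s = HealthState
    m[s.NO_CVD, s.POST_CHD] = probs["chd_nf"][0]
    m[s.NO_CVD, s.POST_STROKE] = probs["stroke_nf"][0]
    m[s.NO_CVD, s.DEAD_CVD] = probs["chd_f"][0] + probs["stroke_f"][0]
    m[s.NO_CVD, s.DEAD_OTHER] = probs["q_other"][0]
    m[s.NO_CVD, s.NO_CVD] = 1.0 - m[s.NO_CVD].sum()
    dest = s.DEAD_CVD if probs["post_death_is_cvd"][0] else s.DEAD_OTHER
    m[s.POST_CHD, dest] = probs["d_chd"][0]
    m[s.POST_CHD, s.POST_CHD] = 1.0 - probs["d_chd"][0]
    m[s.POST_STROKE, dest] = probs["d_stroke"][0]
    m[s.POST_STROKE, s.POST_STROKE] = 1.0 - probs["d_stroke"][0]
    m[s.DEAD_CVD, s.DEAD_CVD] = 1.0
    m[s.DEAD_OTHER, s.DEAD_OTHER] = 1.0
    return m


def _cycle_probabilities(sex, age, p1_chd, p1_stroke, statin, antihyp,
                         params: ParameterSet, k: int) -> dict:
    """Per-person transition probabilities for cycle ``k`` (1-based)."""
    n = len(age)
    at_cap = np.asarray(age) >= params.max_age
    q = np.where(at_cap, 1.0, params.life_table.q(sex, np.minimum(age, params.max_age)))

    in_horizon = k <= params.effect_horizon
    if in_horizon:
        cf = params.effective_case_fatality()
        active = ~at_cap
        frac_chd = np.zeros(n)
        frac_str = np.zeros(n)
        if active.any():
            frac_chd[active] = cf.fraction("chd", np.asarray(sex)[active],
                                           np.asarray(age)[active])
            frac_str[active] = cf.fraction("stroke", np.asarray(sex)[active],
                                           np.asarray(age)[active])
        chd_f = np.where(active, p1_chd * frac_chd, 0.0)
        chd_nf = np.where(active, p1_chd - chd_f, 0.0)
        str_f = np.where(active, p1_stroke * frac_str, 0.0)
        str_nf = np.where(active, p1_stroke - str_f, 0.0)
        chd_f, chd_nf = apply_treatment_effects(chd_f, chd_nf, "chd", statin, antihyp,
                                                params, k)
        str_f, str_nf = apply_treatment_effects(str_f, str_nf, "stroke", statin, antihyp,
                                                params, k)
        total_event = chd_f + chd_nf + str_f + str_nf
        scale = np.where(total_event > 1.0, 1.0 / np.maximum(total_event, 1e-300), 1.0)
        chd_f, chd_nf, str_f, str_nf = (x * scale for x in (chd_f, chd_nf, str_f, str_nf))
        total_event = np.minimum(total_event, 1.0)
        q_other = q * (1.0 - total_event)
        d_chd = np.maximum(params.p_death_post_chd, q)
        d_str = np.maximum(params.p_death_post_stroke, q)
        # a death forced by the age cap is natural, not a CVD death
        post_death_is_cvd = ~at_cap
    else:
        zeros = np.zeros(n)
        chd_f = chd_nf = str_f = str_nf = zeros
        q_other = q
        d_chd = d_str = q
        post_death_is_cvd = np.zeros(n, dtype=bool)

    return {
        "chd_f": chd_f, "chd_nf": chd_nf, "stroke_f": str_f, "stroke_nf": str_nf,
        "q_other": q_other, "d_chd": d_chd, "d_stroke": d_str,
        "post_death_is_cvd": post_death_is_cvd,
    }


def null_plan(index) -> pd.DataFrame:
    """A treatment plan with no medication and no follow-up."""
    plan = pd.DataFrame(index=index)
    for col in PLAN_COLUMNS:
        plan[col] = 0
    for col in ("high_risk", "antihypertensive", "statin", "hypoglycaemic",
                "newly_started_any"):
        plan[col] = plan[col].astype(bool)
    return plan


def simulate_cohort(
    screened: pd.DataFrame,
    plan: pd.DataFrame,
    params: ParameterSet,
    scenario: ScenarioSpec | None = None,
    include_screening_cost: bool = True,
    trace: bool = False,
):
    """Propagate every person in ``screened`` through the Markov model.

    ``screened`` must carry ``p1_chd`` and ``p1_stroke`` (see
    :func:`attach_event_probabilities`).  Returns a DataFrame of
    :data:`OUTCOME_COLUMNS` indexed like ``screened``; with
    ``trace=True`` also returns the occupancy history, an array of shape
    ``(n_cycles + 1, n_persons, 5)``.
    """
    n = len(screened)
    if n == 0:
        empty = pd.DataFrame(columns=OUTCOME_COLUMNS, dtype=float)
        return (empty, np.zeros((1, 0, N_STATES))) if trace else empty

    sex = screened["sex"].to_numpy()
    age0 = np.floor(screened["age"].to_numpy(dtype=float)).astype(int)
    base_u = screened["baseline_utility"].to_numpy(dtype=float)
    p1_chd = screened["p1_chd"].to_numpy(dtype=float)
    p1_str = screened["p1_stroke"].to_numpy(dtype=float)

    statin = plan["statin"].to_numpy(dtype=bool)
    antihyp = plan["antihypertensive"].to_numpy(dtype=bool)
    hypogly = plan["hypoglycaemic"].to_numpy(dtype=bool)
    newly = plan["newly_started_any"].to_numpy(dtype=float)
    fu_init = plan["follow_ups_initial_year"].to_numpy(dtype=float)
    fu_sub = plan["follow_ups_subsequent_years"].to_numpy(dtype=float)
    glu_tests = plan["glucose_tests_per_year"].to_numpy(dtype=float)
    chol_tests = plan["cholesterol_tests_per_year"].to_numpy(dtype=float)

    med_cost = (
        params.cost_statin * statin
        + params.cost_antihypertensive * antihyp
        + params.cost_metformin * hypogly
    )
    usual = _usual_care_costs(params)

    r = params.discount_rate
    disc_q = np.zeros(n)
    disc_c = np.zeros(n)
    undisc_q = np.zeros(n)
    undisc_c = np.zeros(n)
    life_years = np.zeros(n)
    events = {k: np.zeros(n) for k in ("chd_nf", "chd_f", "stroke_nf", "stroke_f")}

    if include_screening_cost and scenario is not None:
        sc = screening_cost(scenario, params)
        disc_c += sc
        undisc_c += sc

    occ = np.zeros((n, N_STATES))
    occ[:, HealthState.NO_CVD] = 1.0
    history = [occ.copy()] if trace else None

    k_max = int(params.max_age - age0.min() + 1)
    for k in range(1, k_max + 1):
        age_k = age0 + (k - 1)
        pr = _cycle_probabilities(sex, age_k, p1_chd, p1_str, statin, antihyp, params, k)

        new = np.empty_like(occ)
        s = HealthState
        from_no = occ[:, s.NO_CVD]
        inc_chd_nf = from_no * pr["chd_nf"]
        inc_chd_f = from_no * pr["chd_f"]
        inc_str_nf = from_no * pr["stroke_nf"]
        inc_str_f = from_no * pr["stroke_f"]
        stay_no = 1.0 - (pr["chd_nf"] + pr["chd_f"] + pr["stroke_nf"] + pr["stroke_f"]
                         + pr["q_other"])
        new[:, s.NO_CVD] = from_no * stay_no
        new[:, s.POST_CHD] = occ[:, s.POST_CHD] * (1.0 - pr["d_chd"]) + inc_chd_nf
        new[:, s.POST_STROKE] = occ[:, s.POST_STROKE] * (1.0 - pr["d_stroke"]) + inc_str_nf
        post_deaths = occ[:, s.POST_CHD] * pr["d_chd"] + occ[:, s.POST_STROKE] * pr["d_stroke"]
        is_cvd = pr["post_death_is_cvd"]
        new[:, s.DEAD_CVD] = occ[:, s.DEAD_CVD] + inc_chd_f + inc_str_f + post_deaths * is_cvd
        new[:, s.DEAD_OTHER] = (occ[:, s.DEAD_OTHER] + from_no * pr["q_other"]
                                + post_deaths * ~is_cvd)

        avg = 0.5 * (occ + new)
        years = k - 1
        u_no = utility_flow(base_u, s.NO_CVD, years, newly, params)
        u_chd = utility_flow(base_u, s.POST_CHD, years, newly, params)
        u_str = utility_flow(base_u, s.POST_STROKE, years, newly, params)
        qaly = (avg[:, s.NO_CVD] * u_no + avg[:, s.POST_CHD] * u_chd
                + avg[:, s.POST_STROKE] * u_str)
        alive_avg = avg[:, list(ALIVE)].sum(axis=1)

        visits = fu_init if k == 1 else fu_sub
        follow = (visits * params.cost_consultation
                  + glu_tests * params.cost_glucose_test
                  + chol_tests * params.cost_cholesterol_test)
        recurring = (med_cost + follow) * alive_avg + (
            avg[:, s.NO_CVD] * usual[0]
            + avg[:, s.POST_CHD] * usual[1]
            + avg[:, s.POST_STROKE] * usual[2]
        )
        admissions = (
            (inc_chd_nf + inc_chd_f) * params.cost_mi_admission
            + (inc_str_nf + inc_str_f) * params.cost_stroke_admission
        )
        cost = recurring + admissions

        df_k = (1.0 + r) ** (-k)
        disc_q += qaly * df_k
        disc_c += cost * df_k
        undisc_q += qaly
        undisc_c += cost
        life_years += alive_avg
        events["chd_nf"] += inc_chd_nf
        events["chd_f"] += inc_chd_f
        events["stroke_nf"] += inc_str_nf
        events["stroke_f"] += inc_str_f

        occ = new
        if trace:
            history.append(occ.copy())
        if occ[:, list(ALIVE)].sum() < 1e-15:
            break

    out = pd.DataFrame(
        {
            "discounted_qalys": disc_q,
            "discounted_costs": disc_c,
            "undiscounted_qalys": undisc_q,
            "undiscounted_costs": undisc_c,
            "life_years": life_years,
            "chd_nonfatal": events["chd_nf"],
            "chd_fatal": events["chd_f"],
            "stroke_nonfatal": events["stroke_nf"],
            "stroke_fatal": events["stroke_f"],
        },
        index=screened.index,
    )
    if trace:
        return out, np.asarray(history)
    return out


def program_effect(
    screened: pd.DataFrame, plan: pd.DataFrame, params: ParameterSet,
    scenario: ScenarioSpec,
) -> pd.DataFrame:
    """Program-attributable outcomes: screened-and-treated minus left-alone.

    Subtracts, per person, the lifetime outcome of the counterfactual in
    which they are never screened (no screening visit, no medication, no
    follow-up) from the outcome under the scenario's treatment plan.
    Scaling these differences to program capacity gives program totals
    that are comparable across designs screening different age ranges —
    a cohort's baseline QALYs cancel instead of swamping the treatment
    effect.
    """
    treated = simulate_cohort(screened, plan, params, scenario,
                              include_screening_cost=True)
    untreated = simulate_cohort(screened, null_plan(screened.index), params,
                                scenario, include_screening_cost=False)
    return treated - untreated


def simulate_individual(
    individual, plan_row, params: ParameterSet,
    scenario: ScenarioSpec | None = None, include_screening_cost: bool = True,
) -> LifetimeOutcome:
    """Single-person wrapper around :func:`simulate_cohort`."""
    df = pd.DataFrame([dict(individual)])
    plan = pd.DataFrame([dict(plan_row)])
    res = simulate_cohort(df, plan, params, scenario, include_screening_cost)
    return LifetimeOutcome(**{c: float(res[c].iloc[0]) for c in OUTCOME_COLUMNS})
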
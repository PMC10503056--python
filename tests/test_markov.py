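import numpy as np
import pandas as pd
import pytest

from cvdscreen.markov import (
    HealthState,
    apply_treatment_effects,
    attach_event_probabilities,
    cost_flow,
    null_plan,
    simulate_cohort,
    simulate_individual,
    transition_matrix,
    utility_flow,
)
from cvdscreen.parameters import LifeTable, ParameterSet
from cvdscreen.policy import base_case, screen_cohort
from .conftest import flat_case_fatality, make_person, simple_params


def plan_row(**cols):
    row = {"high_risk": False, "antihypertensive": False, "statin": False,
           "hypoglycaemic": False, "newly_started_any": False,
           "follow_ups_initial_year": 0, "follow_ups_subsequent_years": 0,
           "glucose_tests_per_year": 0, "cholesterol_tests_per_year": 0}
    row.update(cols)
    row["newly_started_any"] = bool(
        row["antihypertensive"] or row["statin"] or row["hypoglycaemic"]
    )
    return row


def plan_frame(n=1, **cols):
    return pd.DataFrame([plan_row(**cols)] * n)


class TestTreatmentEffects:
    def test_no_medication_identity(self, params):
        pf, pnf = apply_treatment_effects(0.02, 0.05, "chd", False, False, params, 3)
        assert (pf, pnf) == (0.02, 0.05)

    def test_statin_nonfatal_mi(self, params):
        _, pnf = apply_treatment_effects(0.0, 0.10, "chd", True, False, params, 1)
        assert pnf == pytest.approx(0.074)

    def test_multiplicative_composition(self, params):
        _, pnf = apply_treatment_effects(0.0, 0.10, "chd", True, True, params, 5)
        assert pnf == pytest.approx(0.10 * 0.74 * 0.86)

    def test_effect_expires_after_horizon(self, params):
        pf, pnf = apply_treatment_effects(0.02, 0.10, "chd", True, True, params, 11)
        assert (pf, pnf) == (0.02, 0.10)


class TestUtilityFlow:
    def test_no_cvd_year_zero(self, params):
        assert utility_flow(0.9, HealthState.NO_CVD, 0, False, params) == 0.9

    def test_post_stroke_decrement(self, params):
        got = utility_flow(0.9, HealthState.POST_STROKE, 0, False, params)
        assert got == pytest.approx(0.9 - 0.2493)

    def test_age_decrement(self, params):
        got = utility_flow(0.9, HealthState.NO_CVD, 10, False, params)
        assert got == pytest.approx(0.9 - 0.066)

    def test_pill_disutility(self):
        p = ParameterSet(pill_disutility=0.00384)
        got = utility_flow(0.9, HealthState.NO_CVD, 0, True, p)
        assert got == pytest.approx(0.9 - 0.00384)

    def test_floor(self, params):
        assert utility_flow(-0.5, HealthState.POST_STROKE, 100, False, params) == -1.0


class TestCostFlow:
    def test_untreated_no_usual_care_is_free(self):
        p = simple_params()
        assert cost_flow(HealthState.NO_CVD, 2, plan_row(), p) == 0.0

    def test_statin_subsequent_year(self):
        p = simple_params()
        plan = plan_row(statin=True, follow_ups_initial_year=2,
                        follow_ups_subsequent_years=1, glucose_tests_per_year=1)
        expected = 3.98 + 1 * 1.96 + 1 * 0.17
        assert cost_flow(HealthState.NO_CVD, 2, plan, p) == pytest.approx(expected)

    def test_initial_year_extra_visit(self):
        p = simple_params()
        plan = plan_row(statin=True, follow_ups_initial_year=2,
                        follow_ups_subsequent_years=1, glucose_tests_per_year=1)
        first = cost_flow(HealthState.NO_CVD, 1, plan, p)
        later = cost_flow(HealthState.NO_CVD, 2, plan, p)
        assert first - later == pytest.approx(1.96)

    def test_usual_care_ratios(self, params):
        c_no = cost_flow(HealthState.NO_CVD, 2, plan_row(), params)
        c_chd = cost_flow(HealthState.POST_CHD, 2, plan_row(), params)
        inp, outp = params.usual_care_inpatient, params.usual_care_outpatient
        assert c_no == pytest.approx(inp + outp)
        assert c_chd == pytest.approx(inp * 2.85 + outp * 1.95)

    def test_dead_states_cost_nothing(self, params):
        assert cost_flow(HealthState.DEAD_CVD, 2, plan_row(statin=True), params) == 0.0


class TestTransitionMatrix:
    def test_zero_risk_identity(self):
        p = simple_params(p_death_post_chd=0.0, p_death_post_stroke=0.0)
        m = transition_matrix("female", 50, 0.0, 0.0, plan_row(), p, 1)
        np.testing.assert_allclose(m, np.eye(5))

    def test_rows_sum_to_one(self):
        p = simple_params(life_table=LifeTable.flat(0.01))
        m = transition_matrix("female", 60, 0.04, 0.03, plan_row(statin=True), p, 2)
        np.testing.assert_allclose(m.sum(axis=1), np.ones(5), atol=1e-12)

    def test_forced_absorption_at_max_age(self):
        p = simple_params()
        m = transition_matrix("female", 100, 0.04, 0.03, plan_row(), p, 1)
        for s in (HealthState.NO_CVD, HealthState.POST_CHD, HealthState.POST_STROKE):
            assert m[s, HealthState.DEAD_OTHER] == 1.0

    def test_event_split_row(self):
        """NO_CVD row reproduces the fatal/non-fatal split and the
        competing-risk natural mortality on the event-free remainder."""
        p = simple_params(life_table=LifeTable.flat(0.01), case_fatality=flat_case_fatality(0.3))
        m = transition_matrix("female", 60, 0.04, 0.0, plan_row(), p, 1)
        assert m[0, HealthState.POST_CHD] == pytest.approx(0.028)
        assert m[0, HealthState.DEAD_CVD] == pytest.approx(0.012)
        assert m[0, HealthState.DEAD_OTHER] == pytest.approx(0.01 * (1 - 0.04))
        assert m[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_post_event_mortality_floor(self):
        """Post-event death probabilities floor at natural mortality."""
        p = simple_params(life_table=LifeTable.flat(0.5))
        m = transition_matrix("female", 60, 0.0, 0.0, plan_row(), p, 2)
        assert m[HealthState.POST_CHD, HealthState.DEAD_CVD] == 0.5
        assert m[HealthState.POST_STROKE, HealthState.DEAD_CVD] == 0.5

    def test_after_horizon_natural_mortality_only(self):
        p = simple_params(life_table=LifeTable.flat(0.02))
        m = transition_matrix("female", 60, 0.5, 0.5, plan_row(), p, 11)
        assert m[0, HealthState.POST_CHD] == 0.0
        assert m[HealthState.POST_CHD, HealthState.DEAD_OTHER] == pytest.approx(0.02)


def sim_person(params, plan_cols=None, **person_cols):
    person = make_person(**person_cols)
    person["p1_chd"] = person_cols.get("p1_chd", 0.0)
    person["p1_stroke"] = person_cols.get("p1_stroke", 0.0)
    plan = plan_frame(**(plan_cols or {}))
    return simulate_cohort(person, plan, params, include_screening_cost=False)


class TestSimulate:
    def test_qalys_equal_survival_time_in_conservation_limit(self):
        """Perfect health, no mortality, no discounting: QALYs accrue one
        per full year alive, plus the half-cycle credit in the forced
        terminal cycle at the age cap."""
        p = simple_params(discount_rate=0.0, max_age=70)
        out = sim_person(p, age=60.0, baseline_utility=1.0)
        t = 70 - 60
        assert out["undiscounted_qalys"].iloc[0] == pytest.approx(t + 0.5, abs=1e-12)
        assert out["life_years"].iloc[0] == pytest.approx(t + 0.5, abs=1e-12)

    def test_discounted_equals_undiscounted_at_zero_rate(self):
        p = simple_params(discount_rate=0.0, life_table=LifeTable.flat(0.05))
        out = sim_person(p, age=60.0, p1_chd=0.02)
        assert out["discounted_qalys"].iloc[0] == out["undiscounted_qalys"].iloc[0]
        assert out["discounted_costs"].iloc[0] == out["undiscounted_costs"].iloc[0]

    @pytest.mark.parametrize("r", [0.0, 0.03, 0.06])
    def test_half_cycle_discounting_closed_form(self, r):
        """Constant utility flow with certain survival matches the
        geometric sum  sum_k u (1+r)^-k  plus the terminal half-cycle
        term, to 1e-10."""
        u = 0.8
        p = simple_params(discount_rate=r, max_age=70)
        out = sim_person(p, age=60.0, baseline_utility=u)
        t = 10
        v = 1.0 / (1.0 + r)
        expected = u * sum(v**k for k in range(1, t + 1)) + 0.5 * u * v ** (t + 1)
        assert abs(out["discounted_qalys"].iloc[0] - expected) <= 1e-10

    def test_neutral_treatment_changes_nothing_but_followup_costs(self):
        """With all RRs at 1 and free medication, the treated run gains
        exactly zero QALYs over the untreated run."""
        p = simple_params(
            life_table=LifeTable.flat(0.02),
            rr_statin_nonfatal_chd=1.0, rr_statin_nonfatal_stroke=1.0,
            rr_statin_fatal_chd=1.0, rr_statin_fatal_stroke=1.0,
            rr_antihyp_nonfatal_chd=1.0, rr_antihyp_nonfatal_stroke=1.0,
            rr_antihyp_fatal_chd=1.0, rr_antihyp_fatal_stroke=1.0,
            cost_statin=0.0, cost_enalapril=0.0, cost_nifedipine=0.0,
            cost_metformin=0.0,
        )
        person = make_person(age=55.0)
        person["p1_chd"], person["p1_stroke"] = 0.03, 0.02
        treated = simulate_cohort(
            person, plan_frame(statin=True, antihypertensive=True,
                               follow_ups_subsequent_years=1, glucose_tests_per_year=1),
            p, include_screening_cost=False,
        )
        untreated = simulate_cohort(person, null_plan(person.index), p,
                                    include_screening_cost=False)
        assert treated["discounted_qalys"].iloc[0] == untreated["discounted_qalys"].iloc[0]
        assert treated["discounted_costs"].iloc[0] > untreated["discounted_costs"].iloc[0]

    def test_weaker_treatment_gains_fewer_qalys(self):
        person = make_person(age=55.0)
        person["p1_chd"], person["p1_stroke"] = 0.04, 0.03
        gains = []
        for rr in (0.74, 0.9, 1.0):
            p = simple_params(
                life_table=LifeTable.flat(0.01),
                rr_statin_nonfatal_chd=rr, rr_statin_fatal_chd=rr,
                rr_statin_nonfatal_stroke=rr, rr_statin_fatal_stroke=rr,
            )
            treated = simulate_cohort(person, plan_frame(statin=True), p,
                                      include_screening_cost=False)
            untreated = simulate_cohort(person, null_plan(person.index), p,
                                        include_screening_cost=False)
            gains.append(treated["discounted_qalys"].iloc[0]
                         - untreated["discounted_qalys"].iloc[0])
        assert gains[0] > gains[1] > gains[2] == pytest.approx(0.0, abs=1e-14)

    def test_occupancy_conserved_and_death_monotone(self, pop500, params):
        scen = base_case()
        screened, plan, _ = screen_cohort(pop500, scen)
        screened = attach_event_probabilities(screened)
        _, occ = simulate_cohort(screened.head(50), plan.head(50), params, scen, trace=True)
        sums = occ.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        dead = occ[:, :, 3] + occ[:, :, 4]
        assert np.all(np.diff(dead, axis=0) >= -1e-15)

    def test_bit_identical_reruns(self, pop500, params):
        scen = base_case()
        screened, plan, _ = screen_cohort(pop500, scen)
        screened = attach_event_probabilities(screened)
        a = simulate_cohort(screened, plan, params, scen)
        b = simulate_cohort(screened, plan, params, scen)
        pd.testing.assert_frame_equal(a, b)

    def test_screening_cost_added_once(self):
        p = simple_params(max_age=56)
        scen = base_case().with_(mode="lab")
        person = make_person(age=55.0)
        person["p1_chd"], person["p1_stroke"] = 0.0, 0.0
        with_sc = simulate_cohort(person, null_plan(person.index), p, scen)
        without = simulate_cohort(person, null_plan(person.index), p, scen,
                                  include_screening_cost=False)
        diff = with_sc["undiscounted_costs"].iloc[0] - without["undiscounted_costs"].iloc[0]
        assert diff == pytest.approx(1.96 + 0.17 + 0.19)

    def test_simulate_individual_matches_cohort(self, params):
        person = make_person(age=60.0)
        person["p1_chd"], person["p1_stroke"] = 0.02, 0.01
        out = simulate_individual(person.iloc[0], plan_row(statin=True), params)
        cohort = simulate_cohort(person, plan_frame(statin=True), params,
                                 include_screening_cost=False)
        assert out.discounted_qalys == cohort["discounted_qalys"].iloc[0]
        assert out.discounted_costs == cohort["discounted_costs"].iloc[0]

    def test_event_admission_costs_counted(self):
        p = simple_params(discount_rate=0.0, life_table=LifeTable.flat(0.0), max_age=66)
        person = make_person(age=55.0)
        person["p1_chd"], person["p1_stroke"] = 0.02, 0.01
        out = simulate_cohort(person, null_plan(person.index), p,
                              include_screening_cost=False)
        expected = (
            (out["chd_nonfatal"] + out["chd_fatal"]) * 318.0
            + (out["stroke_nonfatal"] + out["stroke_fatal"]) * 241.0
        ).iloc[0]
        assert out["undiscounted_costs"].iloc[0] == pytest.approx(expected)
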
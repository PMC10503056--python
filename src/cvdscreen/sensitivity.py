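"""Deterministic and probabilistic sensitivity analysis.

Parameter uncertainty is encoded per quantity as a
:class:`ParameterDistribution` matching the families health-economic
models conventionally use:

* ``point`` — no uncertainty;
* ``uniform_pct`` — uniform on ``value * (1 ± half_width)``;
* ``lognormal_from_ci`` — log-normal with median at the point estimate
  and ``sigma_log = (ln hi - ln lo) / (2 * 1.959964)`` from a 95% CI
  (used for relative risks and cost-inflation ratios);
* ``beta_from_ci`` — beta with moments matched to the point estimate and
  ``sd = (hi - lo) / (2 * 1.959964)`` (probabilities);
* ``gamma_mean_sd`` — gamma parameterised by mean and an SD fraction
  (costs);
* ``neg_lognormal_from_ci`` — for utility decrements: sampled log-normal
  on the negated (positive-magnitude) scale, with a deterministic
  location shift when the CI crosses zero.

The probabilistic analysis draws one full parameter realisation per
iteration and applies it to *all* scenarios (common random parameters),
then summarises cost-effectiveness acceptability curves by net monetary
benefit and the probability that each scenario's ICER against the base
falls below a stated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import COST_SAVING, incremental, scale_to_program
from .markov import attach_event_probabilities, program_effect, simulate_cohort
from .parameters import ParameterSet
from .policy import ScenarioSpec, screen_cohort

#: two-sided 95% normal score divisor
Z95 = 2 * 1.959964


class DistributionError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling recipe for one scalar parameter of :class:`ParameterSet`."""

    name: str
    family: str
    value: float
    lo: float | None = None
    hi: float | None = None
    half_width: float | None = None   # fraction, for uniform_pct
    sd_fraction: float | None = None  # for gamma_mean_sd

    def __post_init__(self):
        if self.family in ("lognormal_from_ci", "beta_from_ci", "neg_lognormal_from_ci"):
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise DistributionError(f"{self.name}: CI bounds must satisfy lo < hi")
        if self.family == "uniform_pct" and (self.half_width is None or self.half_width < 0):
            raise DistributionError(f"{self.name}: half_width must be >= 0")
        if self.family == "gamma_mean_sd" and (self.sd_fraction is None or self.sd_fraction <= 0):
            raise DistributionError(f"{self.name}: sd_fraction must be > 0")

    def draw(self, rng: np.random.Generator, size=None):
        v = self.value
        if self.family == "point":
            return v if size is None else np.full(size, v)
        if self.family == "uniform_pct":
            w = v * self.half_width
            return rng.uniform(v - w, v + w, size=size)
        if self.family == "lognormal_from_ci":
            sdlog = (np.log(self.hi) - np.log(self.lo)) / Z95
            return rng.lognormal(mean=np.log(v), sigma=sdlog, size=size)
        if self.family == "beta_from_ci":
            sd = (self.hi - self.lo) / Z95
            var = sd**2
            if var >= v * (1 - v):
                raise DistributionError(
                    f"{self.name}: beta moment match infeasible (sd too large)"
                )
            nu = v * (1 - v) / var - 1.0
            return rng.beta(v * nu, (1 - v) * nu, size=size)
        if self.family == "gamma_mean_sd":
            f = self.sd_fraction
            shape = 1.0 / f**2
            return rng.gamma(shape, scale=v * f**2, size=size)
        if self.family == "neg_lognormal_from_ci":
            # decrement d (negative) with CI (lo, hi); sample m = shift - d
            # as log-normal.  shift > hi guarantees positive magnitudes
            # even when the CI crosses zero.
            shift = self.hi + 0.1 * (self.hi - self.lo) if self.hi >= 0 else 0.0
            sdlog = (np.log(shift - self.lo) - np.log(shift - self.hi)) / Z95
            m = rng.lognormal(mean=np.log(shift - v), sigma=sdlog, size=size)
            return shift - m
        raise DistributionError(f"unknown distribution family {self.family!r}")


def default_distributions(params: ParameterSet | None = None) -> list[ParameterDistribution]:
    """The study's distribution assignments for every varied parameter."""
    p = params or ParameterSet()
    D = ParameterDistribution
    return [
        D("case_fatality_multiplier", "uniform_pct", 1.0, half_width=0.10),
        D("p_death_post_chd", "beta_from_ci", p.p_death_post_chd, lo=0.01, hi=0.04),
        D("p_death_post_stroke", "uniform_pct", p.p_death_post_stroke, half_width=0.20),
        D("cost_statin", "uniform_pct", p.cost_statin, half_width=0.10),
        D("rr_statin_nonfatal_chd", "lognormal_from_ci", 0.74, lo=0.67, hi=0.81),
        D("rr_statin_nonfatal_stroke", "lognormal_from_ci", 0.86, lo=0.78, hi=0.95),
        D("rr_statin_fatal_chd", "lognormal_from_ci", 0.82, lo=0.75, hi=0.91),
        D("rr_statin_fatal_stroke", "lognormal_from_ci", 0.92, lo=0.80, hi=1.07),
        D("cost_enalapril", "gamma_mean_sd", p.cost_enalapril, sd_fraction=0.10),
        D("cost_nifedipine", "gamma_mean_sd", p.cost_nifedipine, sd_fraction=0.10),
        D("rr_antihyp_nonfatal_chd", "lognormal_from_ci", 0.86, lo=0.76, hi=0.96),
        D("rr_antihyp_nonfatal_stroke", "lognormal_from_ci", 0.86, lo=0.72, hi=1.01),
        D("rr_antihyp_fatal_chd", "lognormal_from_ci", 0.86, lo=0.65, hi=1.14),
        D("rr_antihyp_fatal_stroke", "lognormal_from_ci", 0.86, lo=0.65, hi=1.14),
        D("cost_metformin", "gamma_mean_sd", p.cost_metformin, sd_fraction=0.10),
        D("cost_glucose_test", "gamma_mean_sd", p.cost_glucose_test, sd_fraction=0.10),
        D("cost_cholesterol_test", "gamma_mean_sd", p.cost_cholesterol_test, sd_fraction=0.10),
        D("cost_consultation", "gamma_mean_sd", p.cost_consultation, sd_fraction=0.10),
        D("inflation_general", "uniform_pct", p.inflation_general, half_width=0.20),
        D("inflation_inpatient_chd", "lognormal_from_ci", 2.85, lo=1.79, hi=4.54),
        D("inflation_inpatient_stroke", "lognormal_from_ci", 1.09, lo=0.53, hi=2.26),
        D("inflation_outpatient_chd", "lognormal_from_ci", 1.95, lo=1.45, hi=2.61),
        D("inflation_outpatient_stroke", "lognormal_from_ci", 1.97, lo=0.83, hi=4.69),
        D("cost_mi_admission", "uniform_pct", p.cost_mi_admission, half_width=0.10),
        D("cost_stroke_admission", "uniform_pct", p.cost_stroke_admission, half_width=0.10),
        D("disutility_nonfatal_chd", "neg_lognormal_from_ci", -0.0210, lo=-0.066, hi=0.024),
        D("disutility_nonfatal_stroke", "neg_lognormal_from_ci", -0.2493, lo=-0.340, hi=-0.158),
        D("disutility_age_per_year", "neg_lognormal_from_ci", -0.0066, lo=-0.007, hi=-0.006),
    ]


def draw_parameters(
    distributions: list[ParameterDistribution],
    rng: np.random.Generator | int,
    base: ParameterSet | None = None,
) -> ParameterSet:
    """One :class:`ParameterSet` realisation, reproducible under a seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = base or ParameterSet()
    valid = set(base.scalar_dict())
    overrides = {}
    for dist in distributions:
        if dist.name not in valid:
            raise DistributionError(f"unknown parameter name {dist.name!r}")
        overrides[dist.name] = float(dist.draw(rng))
    return base.with_(**overrides)


# ---------------------------------------------------------------------------
# pipeline runners
# ---------------------------------------------------------------------------


def _program_totals(population, scenario, params, plan_cache=None):
    """Screen, simulate and scale one scenario under one parameter set."""
    if plan_cache is not None and scenario.scenario_id in plan_cache:
        screened, plan = plan_cache[scenario.scenario_id]
    else:
        screened, plan, _ = screen_cohort(population, scenario)
        screened = attach_event_probabilities(screened, params=params)
        if plan_cache is not None:
            plan_cache[scenario.scenario_id] = (screened, plan)
    outcomes = program_effect(screened, plan, params, scenario)
    return scale_to_program(outcomes, screened["survey_weight"], scenario.capacity)


def scenario_icer(population, base_scenario: ScenarioSpec, scenario: ScenarioSpec,
                  params: ParameterSet, plan_cache=None):
    """(d_cost, d_qalys, icer, label) of ``scenario`` vs ``base_scenario``."""
    bt = _program_totals(population, base_scenario, params, plan_cache)
    at = _program_totals(population, scenario, params, plan_cache)
    return incremental(bt["total_cost"], bt["total_qalys"],
                       at["total_cost"], at["total_qalys"])


def one_way(
    population: pd.DataFrame,
    base_scenario: ScenarioSpec,
    scenario: ScenarioSpec,
    params: ParameterSet,
    overrides: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Deterministic one-way sensitivity analysis (tornado table).

    ``overrides`` maps a variation label to a dict of parameter
    overrides; each variation triggers a full pipeline re-run.  The
    returned table always contains the unmodified base row first.
    """
    valid = set(params.scalar_dict())
    rows = []
    plan_cache: dict = {}
    d_cost, d_qalys, icer, label = scenario_icer(
        population, base_scenario, scenario, params, plan_cache
    )
    rows.append({"variation": "base", "incr_cost": d_cost, "incr_qalys": d_qalys,
                 "icer": icer, "label": label})
    for name, ov in overrides.items():
        unknown = set(ov) - valid
        if unknown:
            raise DistributionError(f"variation {name!r}: unknown parameters {sorted(unknown)}")
        d_cost, d_qalys, icer, label = scenario_icer(
            population, base_scenario, scenario, params.with_(**ov), plan_cache
        )
        rows.append({"variation": name, "incr_cost": d_cost, "incr_qalys": d_qalys,
                     "icer": icer, "label": label})
    return pd.DataFrame(rows)


def default_dsa_overrides(params: ParameterSet) -> dict[str, dict[str, float]]:
    """The study's one-way variations.

    The stronger antihypertensive-on-stroke effect (for baselines with
    SBP >= 160 mmHg) is represented by an illustrative RR of 0.73.
    """
    return {
        "antihyp_stroke_stronger": {"rr_antihyp_nonfatal_stroke": 0.73},
        "discount_0pct": {"discount_rate": 0.0},
        "discount_6pct": {"discount_rate": 0.06},
        "mi_disutility_as_stroke": {
            "disutility_nonfatal_chd": params.disutility_nonfatal_stroke
        },
        "usual_care_80pct": {
            "usual_care_inpatient": 0.8 * params.usual_care_inpatient,
            "usual_care_outpatient": 0.8 * params.usual_care_outpatient,
        },
        "usual_care_120pct": {
            "usual_care_inpatient": 1.2 * params.usual_care_inpatient,
            "usual_care_outpatient": 1.2 * params.usual_care_outpatient,
        },
        "cvd_care_ratio_1": {
            "inflation_inpatient_chd": 1.0, "inflation_inpatient_stroke": 1.0,
            "inflation_outpatient_chd": 1.0, "inflation_outpatient_stroke": 1.0,
        },
        "cvd_care_ratio_3": {
            "inflation_inpatient_chd": 3.0, "inflation_inpatient_stroke": 3.0,
            "inflation_outpatient_chd": 3.0, "inflation_outpatient_stroke": 3.0,
        },
    }


@dataclass
class PSAResult:
    """Per-draw program totals, CEAC and threshold probabilities."""

    draws: pd.DataFrame        # columns: draw, scenario_id, total_cost, total_qalys
    ceac: pd.DataFrame         # columns: wtp, scenario_id, probability
    threshold_prob: pd.DataFrame  # scenario_id, probability ICER vs base <= threshold


def run_psa(
    population: pd.DataFrame,
    scenarios: list[ScenarioSpec],
    base_scenario: ScenarioSpec,
    distributions: list[ParameterDistribution],
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    wtp_grid: np.ndarray | None = None,
    icer_threshold: float = 0.5 * 4083.0,
    base_params: ParameterSet | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with common random parameters.

    Within a draw every scenario (and the base) is evaluated under the
    same parameter realisation.  The CEAC reports, per willingness-to-pay
    value, the probability that each scenario maximises net monetary
    benefit (ties split equally).  ``threshold_prob`` is the fraction of
    draws in which a scenario's ICER against the base is at most
    ``icer_threshold`` (cost-saving draws count as below threshold).
    """
    if n_draws < 1:
        raise DistributionError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 2.0 * 4083.0, 41)
    base_params = base_params or ParameterSet()

    all_scen = [base_scenario] + [s for s in scenarios if s.scenario_id != base_scenario.scenario_id]
    # screening classification does not depend on the varied parameters:
    # precompute screened cohorts and plans once per scenario
    plan_cache: dict = {}
    for s in all_scen:
        screened, plan, _ = screen_cohort(population, s)
        screened = attach_event_probabilities(screened, params=base_params)
        plan_cache[s.scenario_id] = (screened, plan)

    records = []
    for d in range(n_draws):
        params_d = draw_parameters(distributions, rng, base_params)
        for s in all_scen:
            screened, plan = plan_cache[s.scenario_id]
            outcomes = program_effect(screened, plan, params_d, s)
            totals = scale_to_program(outcomes, screened["survey_weight"], s.capacity)
            records.append(
                {"draw": d, "scenario_id": s.scenario_id,
                 "total_cost": totals["total_cost"], "total_qalys": totals["total_qalys"]}
            )
    draws = pd.DataFrame(records)

    ids = [s.scenario_id for s in all_scen]
    cost = draws.pivot(index="draw", columns="scenario_id", values="total_cost")[ids].to_numpy()
    qaly = draws.pivot(index="draw", columns="scenario_id", values="total_qalys")[ids].to_numpy()

    ceac_rows = []
    for wtp in wtp_grid:
        nmb = wtp * qaly - cost
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        share = is_best / is_best.sum(axis=1, keepdims=True)
        for j, sid in enumerate(ids):
            ceac_rows.append({"wtp": float(wtp), "scenario_id": sid,
                              "probability": float(share[:, j].mean())})
    ceac = pd.DataFrame(ceac_rows)

    base_idx = ids.index(base_scenario.scenario_id)
    thr_rows = []
    for j, sid in enumerate(ids):
        if j == base_idx:
            continue
        d_cost = cost[:, j] - cost[:, base_idx]
        d_qaly = qaly[:, j] - qaly[:, base_idx]
        below = (d_cost <= 0) | ((d_qaly > 0) & (d_cost / np.where(d_qaly > 0, d_qaly, 1.0)
                                                 <= icer_threshold))
        thr_rows.append({"scenario_id": sid, "probability": float(below.mean())})
    threshold_prob = pd.DataFrame(thr_rows)

    return PSAResult(draws=draws, ceac=ceac, threshold_prob=threshold_prob)


def pill_disutility_analysis(
    population: pd.DataFrame,
    scenarios: list[ScenarioSpec],
    base_scenario: ScenarioSpec,
    params: ParameterSet,
    disutility: float = 0.00384,
) -> pd.DataFrame:
    """Compare scenario ICERs with and without the pill disutility.

    Returns one row per scenario with increments and ICERs in the main
    analysis and with a utility decrement applied to everyone newly on
    daily medication.
    """
    if disutility < 0:
        raise DistributionError("pill disutility must be >= 0")
    rows = []
    cache_off: dict = {}
    cache_on: dict = {}
    params_on = params.with_(pill_disutility=disutility)
    for s in scenarios:
        if s.scenario_id == base_scenario.scenario_id:
            continue
        d_cost0, d_q0, icer0, lab0 = scenario_icer(
            population, base_scenario, s, params, cache_off
        )
        d_cost1, d_q1, icer1, lab1 = scenario_icer(
            population, base_scenario, s, params_on, cache_on
        )
        rows.append({
            "scenario_id": s.scenario_id,
            "incr_qalys": d_q0, "icer": icer0, "label": lab0,
            "incr_qalys_pill": d_q1, "icer_pill": icer1, "label_pill": lab1,
            "d_incr_qalys": d_q1 - d_q0,
        })
    return pd.DataFrame(rows)
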
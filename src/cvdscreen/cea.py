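"""Incremental cost-effectiveness analysis over a scenario grid.

Per-person lifetime outcomes are scaled to program level (survey-weighted
mean per screened person times one year's screening throughput), compared
against the base case, and screened for dominance:

* **strong dominance** — another scenario yields at least as many QALYs
  at no greater cost, with at least one strict inequality;
* **weak (extended) dominance** — a scenario is removed when pairwise
  ICERs along the cost-ordered survivors fail to increase strictly.

The survivors form the cost-effectiveness frontier, along which each
member's ICER is computed against the closest less costly frontier
member.  ICERs can also be classified against GDP-per-capita multiples
(0.25x / 0.5x / 1x of USD 4,083 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 2019 GDP per capita in current USD used for threshold classification.
GDP_PER_CAPITA = 4083.0

COST_SAVING = "cost_saving"
DOMINATED_STRONG = "dominated_strong"
DOMINATED_WEAK = "dominated_weak"
ON_FRONTIER = "frontier"
BASE = "base"
UNDEFINED = "undefined"


class CEAError(ValueError):
    pass


@dataclass
class ScenarioResult:
    """Program-level totals and increments vs the base case."""

    scenario_id: str
    total_cost: float
    total_qalys: float
    commencement: dict = field(default_factory=dict)
    incr_cost: float = 0.0
    incr_qalys: float = 0.0
    icer: float | None = None
    label: str = ""
    icer_vs_frontier: float | None = None


def scale_to_program(outcomes: pd.DataFrame, weights, capacity: float) -> dict:
    """Weighted mean per screened person times program capacity.

    Returns program totals for discounted cost and QALYs plus expected
    event counts.  Doubling all weights leaves the totals unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) == 0 or w.sum() <= 0:
        raise CEAError("total survey weight must be positive")

    def wmean(col):
        return float(np.average(outcomes[col].to_numpy(dtype=float), weights=w))

    return {
        "total_cost": capacity * wmean("discounted_costs"),
        "total_qalys": capacity * wmean("discounted_qalys"),
        "total_life_years": capacity * wmean("life_years"),
        "events_chd": capacity * (wmean("chd_nonfatal") + wmean("chd_fatal")),
        "events_stroke": capacity * (wmean("stroke_nonfatal") + wmean("stroke_fatal")),
    }


def incremental(base_cost, base_qalys, alt_cost, alt_qalys):
    """Increments and ICER of an alternative vs a comparator.

    Returns ``(d_cost, d_qalys, icer, label)``.  Quadrant conventions:
    north-east → a positive ICER (cost per QALY gained); south-west →
    ``cost_saving`` with the ratio reported as savings per QALY forgone;
    south-east (cheaper and more effective) → ``cost_saving`` with no
    ratio; ``d_qalys == 0`` → ICER undefined.
    """
    d_cost = alt_cost - base_cost
    d_qalys = alt_qalys - base_qalys
    if d_qalys == 0:
        return d_cost, d_qalys, None, UNDEFINED if d_cost != 0 else BASE
    icer = d_cost / d_qalys
    if d_cost < 0 <= d_qalys or d_cost <= 0 < d_qalys:
        return d_cost, d_qalys, None, COST_SAVING
    if d_cost < 0 and d_qalys < 0:
        return d_cost, d_qalys, icer, COST_SAVING
    return d_cost, d_qalys, icer, ""


def dominance_and_frontier(results: list[ScenarioResult]) -> list[ScenarioResult]:
    """Label every scenario and return the cost-effectiveness frontier.

    Mutates ``results`` in place (labels, frontier ICERs) and returns the
    frontier ordered by increasing cost.  Ties in cost and QALYs keep the
    lexicographically smaller scenario id.
    """
    if not results:
        return []
    order = sorted(results, key=lambda x: (x.total_cost, -x.total_qalys, x.scenario_id))

    # strong dominance: more-or-equal QALYs at less-or-equal cost
    survivors: list[ScenarioResult] = []
    for cand in order:
        dominated = False
        for other in results:
            if other is cand:
                continue
            if (
                other.total_cost <= cand.total_cost
                and other.total_qalys >= cand.total_qalys
                and (
                    other.total_cost < cand.total_cost
                    or other.total_qalys > cand.total_qalys
                    or other.scenario_id < cand.scenario_id  # exact tie
                )
            ):
                dominated = True
                break
        if dominated:
            cand.label = DOMINATED_STRONG
        else:
            survivors.append(cand)

    # extended dominance: prune until pairwise ICERs strictly increase
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            lo, mid, hi = survivors[i - 1], survivors[i], survivors[i + 1]
            icer_lo = _pair_icer(lo, mid)
            icer_hi = _pair_icer(mid, hi)
            if icer_lo is not None and icer_hi is not None and icer_lo >= icer_hi:
                mid.label = DOMINATED_WEAK
                del survivors[i]
                changed = True
                break

    for i, res in enumerate(survivors):
        res.label = res.label or ON_FRONTIER
        res.icer_vs_frontier = None if i == 0 else _pair_icer(survivors[i - 1], res)
    return survivors


def _pair_icer(cheap: ScenarioResult, dear: ScenarioResult) -> float | None:
    dq = dear.total_qalys - cheap.total_qalys
    if dq == 0:
        return math.inf if dear.total_cost > cheap.total_cost else None
    return (dear.total_cost - cheap.total_cost) / dq


def threshold_classify(icer, label: str = "", gdp_per_capita: float = GDP_PER_CAPITA,
                       multipliers=(0.25, 0.5, 1.0)) -> str:
    """Classify an ICER against GDP-per-capita multiples.

    Cost-saving results are classified as such before any threshold; an
    ICER exactly on a boundary falls in the lower class (inclusive).
    """
    if label == COST_SAVING:
        return COST_SAVING
    if icer is None:
        return UNDEFINED
    for m in sorted(multipliers):
        if icer <= m * gdp_per_capita:
            return f"le_{m:g}x_gdp"
    return "above_1x_gdp"


def build_cea_table(
    base_totals: dict,
    scenario_totals: dict[str, dict],
    commencement: dict[str, dict] | None = None,
) -> list[ScenarioResult]:
    """Assemble :class:`ScenarioResult` rows (base first) from totals."""
    results = [
        ScenarioResult("base", base_totals["total_cost"], base_totals["total_qalys"],
                       (commencement or {}).get("base", {}), 0.0, 0.0, None, BASE)
    ]
    for sid, totals in scenario_totals.items():
        if sid == "base":
            continue
        d_cost, d_qalys, icer, label = incremental(
            base_totals["total_cost"], base_totals["total_qalys"],
            totals["total_cost"], totals["total_qalys"],
        )
        results.append(
            ScenarioResult(sid, totals["total_cost"], totals["total_qalys"],
                           (commencement or {}).get(sid, {}),
                           d_cost, d_qalys, icer, label)
        )
    return results


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "scenario_id": r.scenario_id,
            "total_cost": r.total_cost,
            "total_qalys": r.total_qalys,
            "incr_cost": r.incr_cost,
            "incr_qalys": r.incr_qalys,
            "icer": r.icer,
            "label": r.label,
            "icer_vs_frontier": r.icer_vs_frontier,
        }
        row.update({k: v for k, v in r.commencement.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def budget_share(incremental_cost: float, annual_budget: float) -> float:
    """Incremental program cost as a percentage of a health budget."""
    if annual_budget <= 0:
        raise CEAError("annual budget must be positive")
    return 100.0 * incremental_cost / annual_budget


def subgroup_by_age(
    base_outcomes: pd.DataFrame,
    alt_outcomes: pd.DataFrame,
    ages,
    weights,
    capacity: float,
    band_width: int = 5,
) -> pd.DataFrame:
    """Incremental cost, QALYs and ICER per half-open age band.

    Both outcome frames must be indexed by the same persons (the
    intersection is used, so scenarios with different age rules compare
    on the commonly screened persons).  Empty bands are omitted.
    """
    common = base_outcomes.index.intersection(alt_outcomes.index)
    ages = pd.Series(np.asarray(ages, dtype=float), index=base_outcomes.index).loc[common]
    w = pd.Series(np.asarray(weights, dtype=float), index=base_outcomes.index).loc[common]
    lo = np.floor(ages / band_width).astype(int) * band_width
    rows = []
    for band in sorted(lo.unique()):
        idx = common[lo == band]
        if len(idx) == 0 or w.loc[idx].sum() <= 0:
            continue
        bt = scale_to_program(base_outcomes.loc[idx], w.loc[idx], capacity)
        at = scale_to_program(alt_outcomes.loc[idx], w.loc[idx], capacity)
        d_cost, d_qalys, icer, label = incremental(
            bt["total_cost"], bt["total_qalys"], at["total_cost"], at["total_qalys"]
        )
        rows.append(
            {"age_lo": band, "age_hi": band + band_width, "n": len(idx),
             "incr_cost": d_cost, "incr_qalys": d_qalys, "icer": icer, "label": label}
        )
    return pd.DataFrame(rows)
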
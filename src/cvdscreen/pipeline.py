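"""End-to-end orchestration: population → screening → Markov → CEA.

:func:`run_pipeline` ties the modules together and writes a reproducible
output bundle (CSV tables, figures, JSON manifest).  All randomness
derives from a single root seed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    build_cea_table,
    dominance_and_frontier,
    results_to_frame,
    scale_to_program,
    threshold_classify,
)
from .markov import attach_event_probabilities, program_effect
from .parameters import ParameterSet
from .policy import ScenarioSpec, base_case, build_scenario_grid, screen_cohort
from .population import PopulationSpec, generate_population, load_population
from .sensitivity import (
    default_distributions,
    default_dsa_overrides,
    one_way,
    run_psa,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record written next to every output bundle."""

    tool_version: str
    timestamp: str
    seed: int
    parameters: dict
    scenario_ids: list[str]
    input_digests: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    outdir,
    seed: int = 0,
    population: pd.DataFrame | None = None,
    population_path=None,
    n_population: int = 5000,
    params: ParameterSet | None = None,
    scenarios: list[ScenarioSpec] | None = None,
    scenario_subset: list[str] | None = None,
    run_dsa: bool = False,
    run_psa_draws: int = 0,
    psa_max_scenarios: int = 5,
    make_figures: bool = True,
) -> dict:
    """Run the full analysis and write the output bundle to ``outdir``.

    Returns a dict with the in-memory results (cea table, frontier,
    screening summaries, optional sensitivity outputs) and the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ParameterSet()
    rng_seeds = np.random.SeedSequence(seed).spawn(2)
    pop_seed = int(rng_seeds[0].generate_state(1)[0] % (2**31))
    psa_seed = int(rng_seeds[1].generate_state(1)[0] % (2**31))

    manifest = RunManifest(
        tool_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        seed=seed,
        parameters=params.scalar_dict(),
        scenario_ids=[],
    )

    if population is None:
        if population_path is not None:
            population = load_population(population_path)
            manifest.input_digests[str(population_path)] = _digest(population_path)
        else:
            population = generate_population(PopulationSpec(n=n_population, seed=pop_seed))

    if scenarios is None:
        scenarios = build_scenario_grid()
    if scenario_subset:
        keep = set(scenario_subset) | {"base"}
        scenarios = [s for s in scenarios if s.scenario_id in keep]
    manifest.scenario_ids = [s.scenario_id for s in scenarios]
    base = next((s for s in scenarios if s.scenario_id == "base"), None)
    if base is None:
        base = base_case()
        scenarios = [base] + scenarios
        manifest.scenario_ids.insert(0, "base")

    # screen + simulate every scenario
    totals: dict[str, dict] = {}
    commencement: dict[str, dict] = {}
    screening_rows = []
    outcome_store: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for s in scenarios:
        screened, plan, summary = screen_cohort(population, s)
        screened = attach_event_probabilities(screened, params=params)
        outcomes = program_effect(screened, plan, params, s)
        totals[s.scenario_id] = scale_to_program(
            outcomes, screened["survey_weight"], s.capacity
        )
        commencement[s.scenario_id] = summary
        outcome_store[s.scenario_id] = (screened, outcomes)
        screening_rows.append({"scenario_id": s.scenario_id, **summary})
        logger.info("scenario %s: %d screened", s.scenario_id, len(screened))

    results = build_cea_table(totals["base"], totals, commencement)
    frontier = dominance_and_frontier(results)
    cea_df = results_to_frame(results)
    cea_df["threshold_class"] = [
        threshold_classify(r.icer, r.label) for r in results
    ]

    screening_df = pd.DataFrame(screening_rows)
    _write(outdir, "screening_summary.csv", screening_df, manifest)
    _write(outdir, "cea_table.csv", cea_df, manifest)
    frontier_df = cea_df[cea_df["scenario_id"].isin([f.scenario_id for f in frontier])]
    _write(outdir, "frontier.csv", frontier_df, manifest)

    bundle = {
        "population": population,
        "scenarios": scenarios,
        "totals": totals,
        "cea_table": cea_df,
        "results": results,
        "frontier": frontier,
        "screening_summary": screening_df,
        "outcomes": outcome_store,
        "manifest": manifest,
    }

    if run_dsa:
        target = frontier[-1] if len(frontier) > 1 else scenarios[-1]
        target_spec = next(s for s in scenarios if s.scenario_id == target.scenario_id)
        dsa = one_way(population, base, target_spec, params, default_dsa_overrides(params))
        dsa.insert(0, "scenario_id", target.scenario_id)
        _write(outdir, "dsa_tornado.csv", dsa, manifest)
        bundle["dsa"] = dsa

    if run_psa_draws > 0:
        psa_scens = [
            next(s for s in scenarios if s.scenario_id == f.scenario_id)
            for f in frontier
            if f.scenario_id != "base"
        ][:psa_max_scenarios]
        psa = run_psa(
            population, psa_scens, base, default_distributions(params),
            n_draws=run_psa_draws, seed=psa_seed, base_params=params,
        )
        _write(outdir, "psa_draws.csv", psa.draws, manifest)
        _write(outdir, "psa_ceac.csv", psa.ceac, manifest)
        _write(outdir, "psa_threshold_prob.csv", psa.threshold_prob, manifest)
        bundle["psa"] = psa

    if make_figures:
        render_reports(bundle, outdir, manifest)

    manifest.write(outdir / "manifest.json")
    return bundle


def _write(outdir: Path, name: str, df: pd.DataFrame, manifest: RunManifest) -> None:
    path = outdir / name
    df.to_csv(path, index=False)
    manifest.outputs.append(name)


def render_reports(bundle: dict, outdir, manifest: RunManifest | None = None) -> list[str]:
    """Frontier scatter, tornado chart and CEAC figure (where available)."""
    outdir = Path(outdir)
    written = []

    cea_df = bundle["cea_table"]
    frontier_ids = [f.scenario_id for f in bundle["frontier"]]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(cea_df["incr_qalys"], cea_df["incr_cost"] / 1e6, s=18, alpha=0.6,
               label="scenarios")
    front = cea_df[cea_df["scenario_id"].isin(frontier_ids)].sort_values("incr_cost")
    if len(front) > 1:
        ax.plot(front["incr_qalys"], front["incr_cost"] / 1e6, "r-o", ms=4,
                label="frontier")
    ax.set_xlabel("Incremental QALYs vs base case")
    ax.set_ylabel("Incremental cost (million USD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "frontier.svg")
    plt.close(fig)
    written.append("frontier.svg")

    if "dsa" in bundle:
        dsa = bundle["dsa"]
        base_icer = dsa.loc[dsa["variation"] == "base", "icer"].iloc[0]
        rows = dsa[dsa["variation"] != "base"].dropna(subset=["icer"])
        rows = rows.iloc[(rows["icer"] - base_icer).abs().argsort()]
        fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(rows), 4) + 1))
        ax.barh(rows["variation"], rows["icer"] - base_icer, left=base_icer,
                color="steelblue")
        ax.axvline(base_icer, color="k", lw=1)
        ax.set_xlabel("ICER (USD/QALY)")
        fig.tight_layout()
        fig.savefig(outdir / "dsa_tornado.svg")
        plt.close(fig)
        written.append("dsa_tornado.svg")

    if "psa" in bundle:
        ceac = bundle["psa"].ceac
        fig, ax = plt.subplots(figsize=(7, 5))
        for sid, grp in ceac.groupby("scenario_id"):
            ax.plot(grp["wtp"], grp["probability"], label=sid)
        ax.set_xlabel("Willingness to pay (USD/QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "ceac.svg")
        plt.close(fig)
        written.append("ceac.svg")

    if manifest is not None:
        manifest.outputs.extend(written)
    return written
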
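"""Build the scenario grid and apply screening/treatment rules.

The default grid crosses 8 risk tools x 2 age rules x 2 risk thresholds
x 2 statins-for-diabetics x 2 lowered-BP-threshold settings, plus the
base case (current protocol) — 129 program designs in all.  Screening a
cohort returns each person's treatment plan and the survey-weighted
share newly commenced on each medication class.
"""

from cvdscreen import (
    PopulationSpec,
    base_case,
    build_scenario_grid,
    generate_population,
    screen_cohort,
)

grid = build_scenario_grid()
print(f"scenario grid: {len(grid)} designs (incl. base case)")

pop = generate_population(PopulationSpec(n=5000, seed=7))

for scen in [
    base_case(),
    base_case().with_(scenario_id="who2019_40plus", risk_tool="who2019",
                      age_rule="40plus"),
    base_case().with_(scenario_id="expanded", risk_tool="who2019",
                      age_rule="40plus", high_risk_threshold=0.10,
                      statins_all_diabetics=True, lowered_bp_threshold=True),
]:
    screened, plan, summary = screen_cohort(pop, scen)
    print(f"\n{scen.scenario_id}: {len(screened)} of {len(pop)} screened")
    print("  % newly commenced on: "
          + ", ".join(f"{k.removeprefix('pct_')} {v:.1f}%"
                      for k, v in summary.items()))

# More generous rules can only expand the treated set:
print("\n(the expanded design treats a superset of the base case's patients)")
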
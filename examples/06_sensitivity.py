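"""Deterministic and probabilistic sensitivity analysis.

The one-way analysis re-runs the pipeline under named parameter
variations (discount rate 0%/6%, stronger antihypertensive effect,
usual-care cost shifts, ...).  The probabilistic analysis draws full
parameter realisations from the per-parameter distributions and
summarises how often each design maximises net monetary benefit.
"""

import numpy as np

from cvdscreen import (
    ParameterSet,
    PopulationSpec,
    base_case,
    default_distributions,
    default_dsa_overrides,
    generate_population,
    one_way,
    run_psa,
)
from cvdscreen.cea import GDP_PER_CAPITA

pop = generate_population(PopulationSpec(n=1500, seed=3))
params = ParameterSet()
alt = base_case().with_(
    scenario_id="who2019_expanded", risk_tool="who2019", age_rule="40plus",
    high_risk_threshold=0.10, statins_all_diabetics=True,
    lowered_bp_threshold=True,
)

print("one-way sensitivity of the expanded WHO-2019 design vs base:\n")
tornado = one_way(pop, base_case(), alt, params, default_dsa_overrides(params))
for _, row in tornado.iterrows():
    icer = f"${row.icer:,.0f}/QALY" if row.icer == row.icer else row.label
    print(f"  {row.variation:26s} {icer}")

print("\nprobabilistic sensitivity (200 draws):")
psa = run_psa(pop, [alt], base_case(), default_distributions(params),
              n_draws=200, seed=5, icer_threshold=0.5 * GDP_PER_CAPITA,
              base_params=params)
p = psa.threshold_prob["probability"].iloc[0]
print(f"  P(ICER vs base <= 0.5 x GDP per capita) = {p:.2f}")
ceac = psa.ceac.pivot(index="wtp", columns="scenario_id", values="probability")
for wtp in (0.25 * GDP_PER_CAPITA, 0.5 * GDP_PER_CAPITA, GDP_PER_CAPITA):
    row = ceac.iloc[np.abs(ceac.index - wtp).argmin()]
    print(f"  at WTP ${wtp:,.0f}: P(expanded design optimal) = "
          f"{row['who2019_expanded']:.2f}")
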
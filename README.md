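# cvdscreen

Cost-effectiveness modelling of cardiovascular disease (CVD) risk
screening program designs, for health-economics and health-policy
analysts working on primary prevention in low-resource settings.

A national screening program must decide who to screen (age rules),
how to assess 10-year CVD risk (office- vs laboratory-based risk
tools), what risk level triggers statins, and whether to extend
treatment rules for diabetics. `cvdscreen` evaluates such designs by:

1. generating a **synthetic survey cohort** with realistic joint
   risk-factor structure (Gaussian-copula coupling, age gradients,
   sex-specific smoking, glucose-consistent diabetes flags);
2. scoring 10-year CHD and stroke risk with **proportional-hazards
   equations** `risk = 1 − S0^exp(Σβ·g(x) − Σβ·g(x̄))` or **banded risk
   charts**, annualised as `p₁ = 1 − (1−p₁₀)^{1/10}`;
3. applying each design's **screening and treatment rules** (BP ≥
   140/90, glucose ≥ 126/200 mg/dL, cholesterol ≥ 300 mg/dL, high-risk
   classification, follow-up schedules);
4. propagating every screened person through a **five-state lifetime
   Markov model** (no CVD, post-CHD, post-stroke, CVD death, other
   death; 1-year cycles, 10-year treatment-effect horizon, half-cycle
   correction, 3% discounting, age cap 100);
5. scaling program-attributable costs and QALYs to one year's
   screening throughput (672,000 persons) and running the **incremental
   cost-effectiveness analysis**: ICERs vs the base case, strong and
   extended dominance, the cost-effectiveness frontier, GDP-per-capita
   threshold classes, and age subgroups;
6. quantifying uncertainty by **deterministic one-way and probabilistic
   sensitivity analysis** (1,000-draw PSA with common random
   parameters, CEAC by net monetary benefit).

The packaged risk-tool coefficients, life table and case-fatality
fractions are clearly-labelled synthetic stand-ins; see
`docs/methods.md` for the model's assumptions and limitations.

## Worked example

```python
from cvdscreen import ParameterSet, run_pipeline
from cvdscreen.policy import build_scenario_grid

grid = build_scenario_grid(tools=[("who_ish", "office"), ("who2019", "office")])
bundle = run_pipeline("results/example_cea", seed=11, n_population=3000,
                      params=ParameterSet(), scenarios=grid)
```

This screens a 3,000-person synthetic cohort under 33 program designs
and prints a frontier like (run `python examples/05_cea_frontier.py`):

```
frontier (7 designs):
                       scenario_id  incr_cost  incr_qalys   icer       label threshold_class
who_ish-office_40plus_t20_SD0_LBP1  2718001.1      2947.5  922.1    frontier    le_0.25x_gdp
who_ish-office_40plus_t10_SD0_LBP1 14865800.3     10220.7 1454.5    frontier     le_0.5x_gdp
who_ish-office_40plus_t10_SD1_LBP1 18050243.1     11263.7 1602.5    frontier     le_0.5x_gdp
who2019-office_35plus_t20_SD0_LBP0 -1385437.9     -1321.6 1048.3 cost_saving     cost_saving
who2019-office_40plus_t20_SD0_LBP0  -620846.7      -453.2 1369.9 cost_saving     cost_saving
who2019-office_40plus_t20_SD0_LBP1  1145218.0      1379.5  830.2    frontier    le_0.25x_gdp
who2019-office_40plus_t10_SD0_LBP1  7550233.3      6751.2 1118.4    frontier     le_0.5x_gdp
```

Reading the rows: `incr_cost` / `incr_qalys` are program totals vs the
base case (current protocol) for one year's screening cohort followed
over its lifetime — e.g. switching the classification tool at unchanged
rules (`who2019-office…t20_SD0_LBP0`) saves about $0.6–1.4 M while
forgoing a small number of QALYs, whereas lowering the high-risk
threshold to 10% with a lowered BP threshold gains several thousand
QALYs at roughly $1,100–1,500 per QALY, i.e. under half a GDP per
capita ($4,083). `label` marks frontier membership and dominance;
dominated designs are in the full `cea_table.csv`.

The other `examples/` scripts walk through each capability one at a
time: population generation, risk scoring, screening rules, the Markov
engine on a single person, and sensitivity analysis. A thin CLI wraps
the same pipeline:

```bash
cvdscreen generate --n 5000 --seed 7 --out pop.csv
cvdscreen all --population pop.csv --outdir results/run1 --psa-draws 200 --dsa
```

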
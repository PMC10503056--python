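"""Score 10-year CVD risk with equation and chart tools.

Equation tools evaluate the sex-specific proportional-hazards survival
form risk = 1 - S0^exp(lp); chart tools place the person in a banded
cell and return the cell's category midpoint.  The annualization helper
converts a 10-year probability to the 1-year probability the Markov
model consumes.
"""

import pandas as pd

from cvdscreen import annualize_probability, load_tool
from cvdscreen.markov import attach_event_probabilities

person = pd.DataFrame([{
    "person_id": 0, "age": 62.0, "sex": "male", "sbp": 158.0, "dbp": 94.0,
    "total_cholesterol": 245.0, "fasting_glucose": 132.0, "random_glucose": 180.0,
    "diabetes": True, "smoker": True, "bmi": 27.0, "baseline_utility": 0.85,
    "survey_weight": 1.0, "prior_cvd": False,
}])

print("10-year combined CVD risk for a 62-year-old male smoker with")
print("diabetes, SBP 158 and total cholesterol 245 mg/dL:\n")
for tool_id in ("who_ish", "who2019", "framingham", "globorisk"):
    for mode in ("office", "lab"):
        tool = load_tool(tool_id, mode)
        risk = float(tool.combined_risk(person)[0])
        print(f"  {tool_id:11s} {mode:6s} {risk:6.1%}")

# Event simulation always uses the lab equation pair (CHD and stroke
# separately), converted to annual probabilities:
scored = attach_event_probabilities(person)
print(f"\nannual CHD probability    {scored.p1_chd[0]:.4f}")
print(f"annual stroke probability {scored.p1_stroke[0]:.4f}")
print(f"\ncheck: a 10-year risk of 20% is an annual risk of "
      f"{annualize_probability(0.20):.4%}")
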
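# Synthetic stand-in tool parameters: structurally faithful to the published
# tool family but NOT the published coefficients.
tool_id: globorisk
mode: lab
kind: equation
outcomes:
  combined_cvd:
    male:
      s0: 0.93
      predictors:
      - name: age
        beta: 0.081
        mean: 52.0
        transform: identity
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 0.017
        mean: 128.0
        transform: identity
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.52
        mean: 0.2
        transform: identity
      - name: diabetes
        beta: 0.6
        mean: 0.12
        transform: identity
      - name: total_cholesterol
        beta: 0.0051
        mean: 200.0
        transform: identity
        lo: 80.0
        hi: 450.0
    female:
      s0: 0.958
      predictors:
      - name: age
        beta: 0.088
        mean: 52.0
        transform: identity
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 0.018
        mean: 128.0
        transform: identity
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.62
        mean: 0.02
        transform: identity
      - name: diabetes
        beta: 0.72
        mean: 0.12
        transform: identity
      - name: total_cholesterol
        beta: 0.0051
        mean: 200.0
        transform: identity
        lo: 80.0
        hi: 450.0
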
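# Synthetic stand-in tool parameters: structurally faithful to the published
# tool family but NOT the published coefficients.
tool_id: who2019
mode: lab
kind: equation
outcomes:
  chd:
    male:
      s0: 0.972
      predictors:
      - name: age
        beta: 0.072
        mean: 52.0
        transform: identity
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 0.016
        mean: 128.0
        transform: identity
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.58
        mean: 0.2
        transform: identity
      - name: diabetes
        beta: 0.62
        mean: 0.12
        transform: identity
      - name: total_cholesterol
        beta: 0.0042
        mean: 200.0
        transform: identity
        lo: 80.0
        hi: 450.0
    female:
      s0: 0.984
      predictors:
      - name: age
        beta: 0.078
        mean: 52.0
        transform: identity
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 0.015
        mean: 128.0
        transform: identity
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.7
        mean: 0.02
        transform: identity
      - name: diabetes
        beta: 0.7
        mean: 0.12
        transform: identity
      - name: total_cholesterol
        beta: 0.0042
        mean: 200.0
        transform: identity
        lo: 80.0
        hi: 450.0
  stroke:
    male:
      s0: 0.988
      predictors:
      - name: age
        beta: 0.083
        mean: 52.0
        transform: identity
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 0.021
        mean: 128.0
        transform: identity
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.42
        mean: 0.2
        transform: identity
      - name: diabetes
        beta: 0.48
        mean: 0.12
        transform: identity
    female:
      s0: 0.991
      predictors:
      - name: age
        beta: 0.086
        mean: 52.0
        transform: identity
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 0.022
        mean: 128.0
        transform: identity
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.5
        mean: 0.02
        transform: identity
      - name: diabetes
        beta: 0.55
        mean: 0.12
        transform: identity
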
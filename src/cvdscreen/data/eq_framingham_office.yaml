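# Synthetic stand-in tool parameters: structurally faithful to the published
# tool family but NOT the published coefficients.
tool_id: framingham
mode: office
kind: equation
outcomes:
  combined_cvd:
    male:
      s0: 0.9
      predictors:
      - name: age
        beta: 3.1
        mean: 52.0
        transform: log
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 1.9
        mean: 128.0
        transform: log
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.65
        mean: 0.2
        transform: identity
      - name: diabetes
        beta: 0.57
        mean: 0.12
        transform: identity
      - name: bmi
        beta: 0.55
        mean: 24.5
        transform: log
        lo: 14.0
        hi: 50.0
    female:
      s0: 0.945
      predictors:
      - name: age
        beta: 3.35
        mean: 52.0
        transform: log
        lo: 35.0
        hi: 95.0
      - name: sbp
        beta: 2.1
        mean: 128.0
        transform: log
        lo: 85.0
        hi: 240.0
      - name: smoker
        beta: 0.75
        mean: 0.02
        transform: identity
      - name: diabetes
        beta: 0.68
        mean: 0.12
        transform: identity
      - name: bmi
        beta: 0.55
        mean: 24.5
        transform: log
        lo: 14.0
        hi: 50.0
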
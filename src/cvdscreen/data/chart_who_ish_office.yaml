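# Synthetic stand-in tool parameters: structurally faithful to the published
# tool family but NOT the published coefficients.
tool_id: who_ish
mode: office
kind: chart
axes:
  age:
  - 35
  - 45
  - 55
  - 65
  - 75
  - 85
  sbp:
  - 100
  - 120
  - 140
  - 160
  - 180
  - 220
categorical:
- sex
- smoker
- diabetes
categories:
- lt10
- r10to20
- r20to30
- r30to40
- ge40
midpoints:
  lt10: 0.05
  r10to20: 0.15
  r20to30: 0.25
  r30to40: 0.35
  ge40: 0.45
cells:
  female|0|0:
  - - 0
    - 0
    - 0
    - 0
    - 0
  - - 0
    - 0
    - 0
    - 0
    - 0
  - - 0
    - 0
    - 0
    - 1
    - 1
  - - 0
    - 1
    - 1
    - 2
    - 3
  - - 1
    - 2
    - 3
    - 4
    - 4
  female|0|1:
  - - 0
    - 0
    - 0
    - 0
    - 0
  - - 0
    - 0
    - 0
    - 1
    - 1
  - - 0
    - 1
    - 1
    - 2
    - 3
  - - 1
    - 2
    - 2
    - 3
    - 4
  - - 3
    - 4
    - 4
    - 4
    - 4
  female|1|0:
  - - 0
    - 0
    - 0
    - 0
    - 0
  - - 0
    - 0
    - 0
    - 0
    - 1
  - - 0
    - 1
    - 1
    - 1
    - 2
  - - 1
    - 2
    - 2
    - 3
    - 4
  - - 2
    - 3
    - 4
    - 4
    - 4
  female|1|1:
  - - 0
    - 0
    - 0
    - 0
    - 1
  - - 0
    - 0
    - 1
    - 1
    - 2
  - - 1
    - 1
    - 2
    - 3
    - 4
  - - 2
    - 3
    - 4
    - 4
    - 4
  - - 4
    - 4
    - 4
    - 4
    - 4
  male|0|0:
  - - 0
    - 0
    - 0
    - 0
    - 0
  - - 0
    - 0
    - 0
    - 0
    - 1
  - - 0
    - 0
    - 1
    - 1
    - 2
  - - 1
    - 1
    - 2
    - 3
    - 4
  - - 2
    - 3
    - 4
    - 4
    - 4
  male|0|1:
  - - 0
    - 0
    - 0
    - 0
    - 1
  - - 0
    - 0
    - 1
    - 1
    - 2
  - - 1
    - 1
    - 2
    - 2
    - 4
  - - 2
    - 2
    - 3
    - 4
    - 4
  - - 4
    - 4
    - 4
    - 4
    - 4
  male|1|0:
  - - 0
    - 0
    - 0
    - 0
    - 1
  - - 0
    - 0
    - 0
    - 1
    - 2
  - - 1
    - 1
    - 1
    - 2
    - 3
  - - 2
    - 2
    - 3
    - 4
    - 4
  - - 3
    - 4
    - 4
    - 4
    - 4
  male|1|1:
  - - 0
    - 0
    - 0
    - 1
    - 1
  - - 0
    - 1
    - 1
    - 2
    - 3
  - - 1
    - 2
    - 3
    - 4
    - 4
  - - 3
    - 4
    - 4
    - 4
    - 4
  - - 4
    - 4
    - 4
    - 4
    - 4
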
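name: exposure_response
nodes:
- name: AcEM
  states:
  - low
  - high
  - perfect
  parents: []
  cpt:
  - given: []
    p:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
- name: AcRM
  states:
  - low
  - high
  - perfect
  parents: []
  cpt:
  - given: []
    p:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
- name: TE
  states:
  - low
  - medium
  - high
  parents: []
  cpt:
  - given: []
    p:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
- name: R
  states:
  - none
  - medium
  - strong
  parents: []
  cpt:
  - given: []
    p:
    - 0.5
    - 0.25
    - 0.25
- name: TR
  states:
  - low
  - medium
  - high
  parents:
  - R
  - TE
  cpt:
  - given:
    - none
    - low
    p:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - given:
    - none
    - medium
    p:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - given:
    - none
    - high
    p:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - given:
    - medium
    - low
    p:
    - 0.6
    - 0.3
    - 0.1
  - given:
    - medium
    - medium
    p:
    - 0.2
    - 0.6
    - 0.2
  - given:
    - medium
    - high
    p:
    - 0.1
    - 0.3
    - 0.6
  - given:
    - strong
    - low
    p:
    - 0.9
    - 0.08
    - 0.02
  - given:
    - strong
    - medium
    p:
    - 0.05
    - 0.9
    - 0.05
  - given:
    - strong
    - high
    p:
    - 0.02
    - 0.08
    - 0.9
- name: ME
  states:
  - low
  - medium
  - high
  parents:
  - AcEM
  - TE
  cpt:
  - given:
    - low
    - low
    p:
    - 0.5
    - 0.3
    - 0.2
  - given:
    - low
    - medium
    p:
    - 0.25
    - 0.5
    - 0.25
  - given:
    - low
    - high
    p:
    - 0.2
    - 0.3
    - 0.5
  - given:
    - high
    - low
    p:
    - 0.8
    - 0.15
    - 0.05
  - given:
    - high
    - medium
    p:
    - 0.1
    - 0.8
    - 0.1
  - given:
    - high
    - high
    p:
    - 0.05
    - 0.15
    - 0.8
  - given:
    - perfect
    - low
    p:
    - 1.0
    - 0.0
    - 0.0
  - given:
    - perfect
    - medium
    p:
    - 0.0
    - 1.0
    - 0.0
  - given:
    - perfect
    - high
    p:
    - 0.0
    - 0.0
    - 1.0
- name: MR
  states:
  - low
  - medium
  - high
  parents:
  - AcRM
  - TR
  cpt:
  - given:
    - low
    - low
    p:
    - 0.5
    - 0.3
    - 0.2
  - given:
    - low
    - medium
    p:
    - 0.25
    - 0.5
    - 0.25
  - given:
    - low
    - high
    p:
    - 0.2
    - 0.3
    - 0.5
  - given:
    - high
    - low
    p:
    - 0.8
    - 0.15
    - 0.05
  - given:
    - high
    - medium
    p:
    - 0.1
    - 0.8
    - 0.1
  - given:
    - high
    - high
    p:
    - 0.05
    - 0.15
    - 0.8
  - given:
    - perfect
    - low
    p:
    - 1.0
    - 0.0
    - 0.0
  - given:
    - perfect
    - medium
    p:
    - 0.0
    - 1.0
    - 0.0
  - given:
    - perfect
    - high
    p:
    - 0.0
    - 0.0
    - 1.0
- name: ERMatch
  states:
  - ll
  - lm
  - lh
  - ml
  - mm
  - mh
  - hl
  - hm
  - hh
  parents:
  - ME
  - MR
  cpt:
  - given:
    - low
    - low
    p:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
  - given:
    - low
    - medium
    p:
    - 0.0
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
  - given:
    - low
    - high
    p:
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
  - given:
    - medium
    - low
    p:
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
  - given:
    - medium
    - medium
    p:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
  - given:
    - medium
    - high
    p:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - 0.0
    - 0.0
  - given:
    - high
    - low
    p:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
    - 0.0
  - given:
    - high
    - medium
    p:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
    - 0.0
  - given:
    - high
    - high
    p:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 1.0
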
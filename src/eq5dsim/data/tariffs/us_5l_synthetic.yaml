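country: US
version: "5L"
full_health_value: 1.0
notes: >
  SYNTHETIC reconstruction of a US EQ-5D-5L value set (additive per-level
  main effects). The anxiety/depression level-5 decrement (0.340) is the
  published anchor; all other coefficients are plausible stand-ins, not the
  national tariff.
terms:
  - {indicator: level_dummy, dimension: MO, level: 2, coefficient: "0.096"}
  - {indicator: level_dummy, dimension: MO, level: 3, coefficient: "0.122"}
  - {indicator: level_dummy, dimension: MO, level: 4, coefficient: "0.237"}
  - {indicator: level_dummy, dimension: MO, level: 5, coefficient: "0.322"}
  - {indicator: level_dummy, dimension: SC, level: 2, coefficient: "0.089"}
  - {indicator: level_dummy, dimension: SC, level: 3, coefficient: "0.107"}
  - {indicator: level_dummy, dimension: SC, level: 4, coefficient: "0.220"}
  - {indicator: level_dummy, dimension: SC, level: 5, coefficient: "0.261"}
  - {indicator: level_dummy, dimension: UA, level: 2, coefficient: "0.068"}
  - {indicator: level_dummy, dimension: UA, level: 3, coefficient: "0.101"}
  - {indicator: level_dummy, dimension: UA, level: 4, coefficient: "0.255"}
  - {indicator: level_dummy, dimension: UA, level: 5, coefficient: "0.258"}
  - {indicator: level_dummy, dimension: PD, level: 2, coefficient: "0.060"}
  - {indicator: level_dummy, dimension: PD, level: 3, coefficient: "0.098"}
  - {indicator: level_dummy, dimension: PD, level: 4, coefficient: "0.318"}
  - {indicator: level_dummy, dimension: PD, level: 5, coefficient: "0.414"}
  - {indicator: level_dummy, dimension: AD, level: 2, coefficient: "0.057"}
  - {indicator: level_dummy, dimension: AD, level: 3, coefficient: "0.123"}
  - {indicator: level_dummy, dimension: AD, level: 4, coefficient: "0.299"}
  - {indicator: level_dummy, dimension: AD, level: 5, coefficient: "0.340"}
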
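country: JP
version: "5L"
full_health_value: 1.0
notes: >
  SYNTHETIC reconstruction of a Japanese EQ-5D-5L value set (additive
  per-level main effects). The anxiety/depression level-5 decrement (0.197)
  is the published anchor; all other coefficients are plausible stand-ins,
  not the national tariff.
terms:
  - {indicator: level_dummy, dimension: MO, level: 2, coefficient: "0.064"}
  - {indicator: level_dummy, dimension: MO, level: 3, coefficient: "0.134"}
  - {indicator: level_dummy, dimension: MO, level: 4, coefficient: "0.191"}
  - {indicator: level_dummy, dimension: MO, level: 5, coefficient: "0.270"}
  - {indicator: level_dummy, dimension: SC, level: 2, coefficient: "0.059"}
  - {indicator: level_dummy, dimension: SC, level: 3, coefficient: "0.108"}
  - {indicator: level_dummy, dimension: SC, level: 4, coefficient: "0.193"}
  - {indicator: level_dummy, dimension: SC, level: 5, coefficient: "0.243"}
  - {indicator: level_dummy, dimension: UA, level: 2, coefficient: "0.053"}
  - {indicator: level_dummy, dimension: UA, level: 3, coefficient: "0.100"}
  - {indicator: level_dummy, dimension: UA, level: 4, coefficient: "0.157"}
  - {indicator: level_dummy, dimension: UA, level: 5, coefficient: "0.180"}
  - {indicator: level_dummy, dimension: PD, level: 2, coefficient: "0.046"}
  - {indicator: level_dummy, dimension: PD, level: 3, coefficient: "0.073"}
  - {indicator: level_dummy, dimension: PD, level: 4, coefficient: "0.155"}
  - {indicator: level_dummy, dimension: PD, level: 5, coefficient: "0.216"}
  - {indicator: level_dummy, dimension: AD, level: 2, coefficient: "0.052"}
  - {indicator: level_dummy, dimension: AD, level: 3, coefficient: "0.079"}
  - {indicator: level_dummy, dimension: AD, level: 4, coefficient: "0.125"}
  - {indicator: level_dummy, dimension: AD, level: 5, coefficient: "0.197"}
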
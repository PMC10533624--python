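country: JP
version: "3L"
full_health_value: 1.0
notes: >
  SYNTHETIC reconstruction of a Japanese EQ-5D-3L value set. Structure
  follows the published Japanese TTO model (an any-dysfunction constant plus
  per-level main effects). The mobility level-3 main-effect decrement
  (0.418) is the published anchor; all other coefficients are plausible
  stand-ins, not the national tariff.
terms:
  - {indicator: any_level_ge, level: 2, coefficient: "0.152"}
  - {indicator: level_dummy, dimension: MO, level: 2, coefficient: "0.075"}
  - {indicator: level_dummy, dimension: MO, level: 3, coefficient: "0.418"}
  - {indicator: level_dummy, dimension: SC, level: 2, coefficient: "0.054"}
  - {indicator: level_dummy, dimension: SC, level: 3, coefficient: "0.102"}
  - {indicator: level_dummy, dimension: UA, level: 2, coefficient: "0.044"}
  - {indicator: level_dummy, dimension: UA, level: 3, coefficient: "0.133"}
  - {indicator: level_dummy, dimension: PD, level: 2, coefficient: "0.080"}
  - {indicator: level_dummy, dimension: PD, level: 3, coefficient: "0.194"}
  - {indicator: level_dummy, dimension: AD, level: 2, coefficient: "0.063"}
  - {indicator: level_dummy, dimension: AD, level: 3, coefficient: "0.112"}
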
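country: NL
version: "5L"
full_health_value: 1.0
notes: >
  SYNTHETIC reconstruction of a Dutch EQ-5D-5L value set (additive per-level
  main effects). The anxiety/depression level-5 decrement (0.421) is the
  published anchor; all other coefficients are plausible stand-ins, not the
  national tariff.
terms:
  - {indicator: level_dummy, dimension: MO, level: 2, coefficient: "0.035"}
  - {indicator: level_dummy, dimension: MO, level: 3, coefficient: "0.057"}
  - {indicator: level_dummy, dimension: MO, level: 4, coefficient: "0.166"}
  - {indicator: level_dummy, dimension: MO, level: 5, coefficient: "0.203"}
  - {indicator: level_dummy, dimension: SC, level: 2, coefficient: "0.038"}
  - {indicator: level_dummy, dimension: SC, level: 3, coefficient: "0.061"}
  - {indicator: level_dummy, dimension: SC, level: 4, coefficient: "0.168"}
  - {indicator: level_dummy, dimension: SC, level: 5, coefficient: "0.170"}
  - {indicator: level_dummy, dimension: UA, level: 2, coefficient: "0.039"}
  - {indicator: level_dummy, dimension: UA, level: 3, coefficient: "0.059"}
  - {indicator: level_dummy, dimension: UA, level: 4, coefficient: "0.161"}
  - {indicator: level_dummy, dimension: UA, level: 5, coefficient: "0.168"}
  - {indicator: level_dummy, dimension: PD, level: 2, coefficient: "0.066"}
  - {indicator: level_dummy, dimension: PD, level: 3, coefficient: "0.083"}
  - {indicator: level_dummy, dimension: PD, level: 4, coefficient: "0.262"}
  - {indicator: level_dummy, dimension: PD, level: 5, coefficient: "0.329"}
  - {indicator: level_dummy, dimension: AD, level: 2, coefficient: "0.070"}
  - {indicator: level_dummy, dimension: AD, level: 3, coefficient: "0.091"}
  - {indicator: level_dummy, dimension: AD, level: 4, coefficient: "0.311"}
  - {indicator: level_dummy, dimension: AD, level: 5, coefficient: "0.421"}
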
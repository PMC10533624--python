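country: US
version: "3L"
full_health_value: 1.0
notes: >
  SYNTHETIC reconstruction of a US EQ-5D-3L value set. Structure follows the
  count-based interaction form of the published US TTO model: per-level main
  effects plus negative-coefficient count terms that attenuate the additive
  decrements when several dimensions are dysfunctional. The mobility level-3
  main-effect decrement (0.490) is the published anchor; all other
  coefficients are plausible stand-ins, not the national tariff.
terms:
  - {indicator: level_dummy, dimension: MO, level: 2, coefficient: "0.146"}
  - {indicator: level_dummy, dimension: MO, level: 3, coefficient: "0.490"}
  - {indicator: level_dummy, dimension: SC, level: 2, coefficient: "0.175"}
  - {indicator: level_dummy, dimension: SC, level: 3, coefficient: "0.471"}
  - {indicator: level_dummy, dimension: UA, level: 2, coefficient: "0.140"}
  - {indicator: level_dummy, dimension: UA, level: 3, coefficient: "0.374"}
  - {indicator: level_dummy, dimension: PD, level: 2, coefficient: "0.173"}
  - {indicator: level_dummy, dimension: PD, level: 3, coefficient: "0.537"}
  - {indicator: level_dummy, dimension: AD, level: 2, coefficient: "0.156"}
  - {indicator: level_dummy, dimension: AD, level: 3, coefficient: "0.450"}
  - {indicator: count_levels_ge, level: 2, offset: 1, coefficient: "-0.140"}
  - {indicator: count_levels_ge, level: 3, offset: 1, coefficient: "-0.163"}
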
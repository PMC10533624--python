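country: NL
version: "3L"
full_health_value: 1.0
notes: >
  SYNTHETIC reconstruction of a Dutch EQ-5D-3L value set. Structure follows
  the published Dutch TTO model (an any-dysfunction constant, per-level main
  effects, and an N3-style term for any dimension at level 3). The mobility
  level-3 main-effect decrement (0.161) is the published anchor; the exact
  published edition of the remaining coefficients is not asserted and they
  should be treated as plausible stand-ins, not the national tariff.
terms:
  - {indicator: any_level_ge, level: 2, coefficient: "0.071"}
  - {indicator: level_dummy, dimension: MO, level: 2, coefficient: "0.036"}
  - {indicator: level_dummy, dimension: MO, level: 3, coefficient: "0.161"}
  - {indicator: level_dummy, dimension: SC, level: 2, coefficient: "0.082"}
  - {indicator: level_dummy, dimension: SC, level: 3, coefficient: "0.152"}
  - {indicator: level_dummy, dimension: UA, level: 2, coefficient: "0.032"}
  - {indicator: level_dummy, dimension: UA, level: 3, coefficient: "0.057"}
  - {indicator: level_dummy, dimension: PD, level: 2, coefficient: "0.086"}
  - {indicator: level_dummy, dimension: PD, level: 3, coefficient: "0.329"}
  - {indicator: level_dummy, dimension: AD, level: 2, coefficient: "0.124"}
  - {indicator: level_dummy, dimension: AD, level: 3, coefficient: "0.325"}
  - {indicator: any_level_ge, level: 3, coefficient: "0.234"}
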
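# direction: 3L_to_5L
# SYNTHETIC crosswalk: adjacent-level transition shape, shared across dimensions; NOT the published crosswalk tables.
dimension,source_level,target_level,probability
MO,1,1,0.85
MO,1,2,0.13
MO,1,3,0.02
MO,1,4,0
MO,1,5,0
MO,2,1,0.05
MO,2,2,0.25
MO,2,3,0.55
MO,2,4,0.14
MO,2,5,0.01
MO,3,1,0
MO,3,2,0.02
MO,3,3,0.18
MO,3,4,0.45
MO,3,5,0.35
SC,1,1,0.85
SC,1,2,0.13
SC,1,3,0.02
SC,1,4,0
SC,1,5,0
SC,2,1,0.05
SC,2,2,0.25
SC,2,3,0.55
SC,2,4,0.14
SC,2,5,0.01
SC,3,1,0
SC,3,2,0.02
SC,3,3,0.18
SC,3,4,0.45
SC,3,5,0.35
UA,1,1,0.85
UA,1,2,0.13
UA,1,3,0.02
UA,1,4,0
UA,1,5,0
UA,2,1,0.05
UA,2,2,0.25
UA,2,3,0.55
UA,2,4,0.14
UA,2,5,0.01
UA,3,1,0
UA,3,2,0.02
UA,3,3,0.18
UA,3,4,0.45
UA,3,5,0.35
PD,1,1,0.85
PD,1,2,0.13
PD,1,3,0.02
PD,1,4,0
PD,1,5,0
PD,2,1,0.05
PD,2,2,0.25
PD,2,3,0.55
PD,2,4,0.14
PD,2,5,0.01
PD,3,1,0
PD,3,2,0.02
PD,3,3,0.18
PD,3,4,0.45
PD,3,5,0.35
AD,1,1,0.85
AD,1,2,0.13
AD,1,3,0.02
AD,1,4,0
AD,1,5,0
AD,2,1,0.05
AD,2,2,0.25
AD,2,3,0.55
AD,2,4,0.14
AD,2,5,0.01
AD,3,1,0
AD,3,2,0.02
AD,3,3,0.18
AD,3,4,0.45
AD,3,5,0.35
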
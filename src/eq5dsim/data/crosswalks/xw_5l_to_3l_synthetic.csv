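# direction: 5L_to_3L
# SYNTHETIC crosswalk: adjacent-level transition shape, shared across dimensions; NOT the published crosswalk tables.
dimension,source_level,target_level,probability
MO,1,1,1
MO,1,2,0
MO,1,3,0
MO,2,1,0.7
MO,2,2,0.3
MO,2,3,0
MO,3,1,0.1
MO,3,2,0.85
MO,3,3,0.05
MO,4,1,0
MO,4,2,0.75
MO,4,3,0.25
MO,5,1,0
MO,5,2,0.15
MO,5,3,0.85
SC,1,1,1
SC,1,2,0
SC,1,3,0
SC,2,1,0.7
SC,2,2,0.3
SC,2,3,0
SC,3,1,0.1
SC,3,2,0.85
SC,3,3,0.05
SC,4,1,0
SC,4,2,0.75
SC,4,3,0.25
SC,5,1,0
SC,5,2,0.15
SC,5,3,0.85
UA,1,1,1
UA,1,2,0
UA,1,3,0
UA,2,1,0.7
UA,2,2,0.3
UA,2,3,0
UA,3,1,0.1
UA,3,2,0.85
UA,3,3,0.05
UA,4,1,0
UA,4,2,0.75
UA,4,3,0.25
UA,5,1,0
UA,5,2,0.15
UA,5,3,0.85
PD,1,1,1
PD,1,2,0
PD,1,3,0
PD,2,1,0.7
PD,2,2,0.3
PD,2,3,0
PD,3,1,0.1
PD,3,2,0.85
PD,3,3,0.05
PD,4,1,0
PD,4,2,0.75
PD,4,3,0.25
PD,5,1,0
PD,5,2,0.15
PD,5,3,0.85
AD,1,1,1
AD,1,2,0
AD,1,3,0
AD,2,1,0.7
AD,2,2,0.3
AD,2,3,0
AD,3,1,0.1
AD,3,2,0.85
AD,3,3,0.05
AD,4,1,0
AD,4,2,0.75
AD,4,3,0.25
AD,5,1,0
AD,5,2,0.15
AD,5,3,0.85
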
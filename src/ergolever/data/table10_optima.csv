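muscle,torso_angle_deg,lever_distance_mm,lever_orientation_deg
BBL,0,50,30
TBL,0,50,0
BRD,0,0,30
PDT,0,50,0
Overall,0,37.5,15
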
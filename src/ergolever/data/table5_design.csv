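run_id,torso_angle_deg,lever_distance_mm,lever_orientation_deg
E1,45,0,-30
E2,45,50,0
E3,45,100,30
E4,30,0,0
E5,30,50,30
E6,30,100,-30
E7,0,0,30
E8,0,50,-30
E9,0,100,0
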
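factor,level,muscle,mean_mvc
torso_angle_deg,0,BBL,38.46
torso_angle_deg,30,BBL,41.93
torso_angle_deg,45,BBL,44.78
torso_angle_deg,0,TBL,47.96
torso_angle_deg,30,TBL,62.91
torso_angle_deg,45,TBL,67.49
torso_angle_deg,0,BRD,72.16
torso_angle_deg,30,BRD,95.20
torso_angle_deg,45,BRD,113.41
torso_angle_deg,0,PDT,50.51
torso_angle_deg,30,PDT,71.25
torso_angle_deg,45,PDT,77.77
lever_distance_mm,0,BBL,42.14
lever_distance_mm,50,BBL,40.47
lever_distance_mm,100,BBL,42.57
lever_distance_mm,0,TBL,60.13
lever_distance_mm,50,TBL,51.30
lever_distance_mm,100,TBL,66.93
lever_distance_mm,0,BRD,89.46
lever_distance_mm,50,BRD,93.53
lever_distance_mm,100,BRD,97.78
lever_distance_mm,0,PDT,72.00
lever_distance_mm,50,PDT,59.67
lever_distance_mm,100,PDT,67.86
lever_orientation_deg,-30,BBL,43.24
lever_orientation_deg,0,BBL,41.14
lever_orientation_deg,30,BBL,40.79
lever_orientation_deg,-30,TBL,62.47
lever_orientation_deg,0,TBL,53.11
lever_orientation_deg,30,TBL,62.78
lever_orientation_deg,-30,BRD,88.01
lever_orientation_deg,0,BRD,106.65
lever_orientation_deg,30,BRD,86.11
lever_orientation_deg,-30,PDT,78.30
lever_orientation_deg,0,PDT,59.58
lever_orientation_deg,30,PDT,61.65
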
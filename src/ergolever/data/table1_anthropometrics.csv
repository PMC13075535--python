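annotation,feature,mean,sd,p5,p95
,age_years,27.5,2.76,23.95,31.1
,height_cm,173.25,3.46,168,178
,weight_kg,71.75,4.98,63.95,78.15
A,hip_width_cm,38.45,3.26,34,42.15
B,buttock_popliteal_length_cm,51,4.41,42.95,56.05
C,popliteal_height_cm,42.1,2.67,38.95,47.05
D,subscapular_height_cm,45.75,2.22,43,50.05
E,shoulder_height_cm,60.85,3.28,54.95,60.85
F,elbow_height_cm,24.85,2.13,22,28.05
G,knee_height_cm,53.95,4.50,48.95,60.15
H,shoulder_width_cm,55.45,4.5,50.85,63.15
I,elbow_fingertip_length_cm,36.35,2.75,33,41.05
J,upper_limb_length_cm,85.4,4.28,78.95,92.1
K,shoulder_grip_length_cm,75.8,5.01,67.95,82.15
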
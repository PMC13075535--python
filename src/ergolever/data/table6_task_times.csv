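task,S1,S2,S3,S4,S5,S6,S7,S8,S9
C,5,4,3.5,3,3.5,4.2,4,3.5,5.3
R,12.7,14.5,15,12.5,14,18,13.8,16.4,16.2
T1,21.4,23,25.4,19.5,20.5,24,20,19,22
F1,6,7.2,8.1,6.3,5,4.5,4.3,4,5.5
R1,1.9,2.5,2,2,2,2,2,2.3,2.8
N,10.4,9.8,6,8,7,9.5,6.5,8.3,9.9
F2,2,2,2,2.8,2,2.5,2,2.2,2.3
R2,5.5,3,3.4,4,4,4,5,3.2,4.4
T2,9.2,7,6,7.3,8.2,9,8.5,7,7
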
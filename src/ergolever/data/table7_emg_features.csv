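run_id,muscle,amplitude,rms,mvc
E1,BBL,69.3,7.8,50.85
E1,TBL,94.4,12.2,69.74
E1,BRD,149.6,22.3,111.41
E1,PDT,132.3,17.4,97.83
E2,BBL,55.5,7.3,41.04
E2,TBL,74.8,10.5,55.51
E2,BRD,179.0,13.24,129.272
E2,PDT,95.0,12.4,70.22
E3,BBL,56.8,9,42.46
E3,TBL,105.2,11.9,77.21
E3,BRD,136.1,14.3,99.56
E3,PDT,88.3,11.5,65.26
E4,BBL,52.9,8.3,39.52
E4,TBL,75.1,12.0,56.17
E4,BRD,128.1,13.0,93.57
E4,PDT,82.6,10.0,60.82
E5,BBL,59.0,8.6,43.88
E5,TBL,76.5,10.3,56.64
E5,BRD,129.8,15.0,95.36
E5,PDT,83.9,12.0,62.33
E6,BBL,56.7,9.0,42.39
E6,TBL,102.5,13.9,75.92
E6,BRD,130.9,16.8,96.67
E6,PDT,121.3,19.0,90.61
E7,BBL,47.8,8.6,36.04
E7,TBL,72.9,11.5,54.48
E7,BRD,85.6,11.6,63.4
E7,PDT,77.6,10.1,57.35
E8,BBL,48.7,8.0,36.49
E8,TBL,55.8,9.0,41.76
E8,BRD,75.1,11.3,55.96
E8,PDT,62.1,10.0,46.47
E9,BBL,56.6,10.8,42.86
E9,TBL,64.0,9.5,47.65
E9,BRD,132.4,14.8,97.12
E9,PDT,64.0,9.7,47.71
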
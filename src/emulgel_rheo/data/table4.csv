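lecithin_fraction,fiber_fraction,gamma_mn_per_m,gamma_sd_mn_per_m
0,0,23.0,0.1
0,0.01,16.0,0.2
1e-9,0,23.0,0.1
0.0001,0,9.43,0.07
0.001,0,3.9,0.1
0.005,0,1.43,0.05
0.005,0.005,1.72,0.03
0.005,0.01,1.4,0.1
0.005,0.015,1.40,0.08
0.01,0,1.40,0.07
0.02,0,1.49,0.08
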
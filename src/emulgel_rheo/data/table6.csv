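sample_id,fiber_fraction,g_r_exp,g_r_exp_sd,modulus_ratio,h_parameter,g_r_model,error_pct
E2.3.0_5.20,0.005,0.6,0.1,0.19,0.190,,
E2.3.1.20,0.01,0.52,0.08,0.081,0.084,2.35,300
E2.3.2.20,0.02,0.38,0.03,0.0084,-0.208,0.37,-4
E2.3.2_5.20,0.025,0.36,0.05,0.0048,-0.253,0.32,-14
E2.3.3.20,0.03,0.29,0.04,0.0037,-0.270,0.30,1
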
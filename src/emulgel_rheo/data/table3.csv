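sample_id,series,fiber_fraction,oil_weight_pct,oil_volume_pct,g_star_pa,g_star_sd_pa,delta_deg,delta_sd_deg
E2.3.3.10,oil,0.03,10,10.8,1600,100,7.6,0.2
E2.3.3.15,oil,0.03,15,16.1,1200,60,7.9,0.1
E2.3.3.20,oil,0.03,20,21.4,870,70,7.3,0.1
E2.3.3.30,oil,0.03,30,31.8,433,30,7.6,0.2
E2.3.3.35,oil,0.03,35,36.9,327,20,8.0,0.3
E2.3.3.40,oil,0.03,40,42.0,340,20,7.3,0.3
E2.3.0_5.20,fiber,0.005,20,21.4,43,3,9.8,0.4
E2.3.1.20,fiber,0.01,20,21.4,70,5,7.1,0.1
E2.3.2.20,fiber,0.02,20,21.4,501,35,8.5,0.1
E2.3.2_5.20,fiber,0.025,20,21.4,830,50,8.4,0.5
E2.3.3.20,fiber,0.03,20,21.4,870,70,7.3,0.1
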
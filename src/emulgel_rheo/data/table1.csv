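sample_id,specific_power_w_per_g,speed_rpm,time_s,fiber_fraction,g_star_pa,g_star_sd_pa,delta_deg,delta_sd_deg,fractal_dimension,fractal_dimension_sd
H_0.5,0.151,8000,300,0.005,57,2,6.77,0.06,2.42,0.01
H_1,0.151,8000,300,0.01,140,10,5.75,0.09,2.444,0.002
H_2,0.151,8000,300,0.02,1310,50,5.3,0.3,2.453,0.005
H_2.5,0.151,8000,300,0.025,2300,200,5.66,0.05,2.438,0.003
H_3,0.151,8000,300,0.03,3000,100,5.57,0.09,2.446,0.007
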
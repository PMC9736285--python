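sample_id,energy_level,specific_energy_j_per_g,specific_power_w_per_g,speed_rpm,time_s,fiber_fraction,g_star_pa,g_star_sd_pa,delta_deg,delta_sd_deg
E1.1.3.20,E1,22.6,0.031,4000,738,0.03,860,40,8.82,0.02
E1.2.3.20,E1,22.6,0.051,5000,442,0.03,840,60,8.2,0.2
E1.3.3.20,E1,22.6,0.078,6000,290,0.03,860,30,7.1,0.1
E1.4.3.20,E1,22.6,0.151,8000,150,0.03,880,90,8.6,0.3
E2.1.1.20,E2,45.2,0.051,5000,886,0.01,39,4,6.6,0.3
E2.2.1.20,E2,45.2,0.078,6000,580,0.01,56,9,6.9,0.1
E2.3.1.20,E2,45.2,0.151,8000,300,0.01,70,5,7.1,0.1
E2.4.1.20,E2,45.2,0.252,10000,179,0.01,70,10,7.4,0.3
E2.1.2.20,E2,45.2,0.051,5000,886,0.02,323,5,7.5,0.6
E2.2.2.20,E2,45.2,0.078,6000,580,0.02,323,2,7.7,0.2
E2.3.2.20,E2,45.2,0.151,8000,300,0.02,500,30,8.51,0.01
E2.4.2.20,E2,45.2,0.252,10000,179,0.02,590,40,8.4,0.1
E2.1.3.20,E2,45.2,0.051,5000,886,0.03,850,120,7.1,0.2
E2.2.3.20,E2,45.2,0.078,6000,580,0.03,860,90,8.4,0.3
E2.3.3.20,E2,45.2,0.151,8000,300,0.03,870,70,7.3,0.1
E2.4.3.20,E2,45.2,0.252,10000,179,0.03,860,100,7.2,0.1
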
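sample_id,d_s_um,d_s_sd_um,sigma_s_um,sigma_s_sd_um
E2.3.1.20,7.1,0.8,6,1
E2.3.3.20,6.5,0.3,4.3,0.1
E2.3.3.30,5.5,0.6,3.1,0.5
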
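region,scenario,total_gwp,total_ep,ch4_enteric,ch4_storage,n2o_direct_storage,n2o_direct_forage,n2o_indirect_storage,n2o_indirect_forage,nh3_in_house,nh3_storage,nh3_forage
oder_spree,Ref,1.01,4.49,0.47,0.080,0.032,0.025,0.021,0.016,0.568,1.038,1.187
oder_spree,SW_low,0.91,4.57,0.33,0.080,0.032,0.025,0.021,0.016,0.568,1.038,1.187
oder_spree,SW_high,0.78,4.66,0.16,0.080,0.032,0.025,0.021,0.016,0.568,1.038,1.187
oder_spree,CT1,1.02,4.29,0.47,0.080,0.032,0.025,0.021,0.016,0.364,1.038,1.187
oder_spree,CT2,0.98,4.03,0.47,0.060,0.025,0.029,0.016,0.016,0.364,0.806,1.190
oder_spree,AS,1.01,4.39,0.47,0.080,0.032,0.019,0.021,0.014,0.568,1.038,0.594
oder_spree,CM,0.75,4.11,0.16,0.060,0.025,0.023,0.016,0.019,0.364,0.806,0.646
diepholz,Ref,1.26,6.09,0.55,0.100,0.038,0.032,0.026,0.021,0.628,1.222,1.742
diepholz,SW_low,1.12,6.18,0.37,0.100,0.038,0.032,0.026,0.021,0.628,1.222,1.742
diepholz,SW_high,0.96,6.27,0.18,0.100,0.038,0.032,0.026,0.021,0.628,1.222,1.742
diepholz,CT1,1.26,5.89,0.55,0.100,0.038,0.032,0.026,0.021,0.424,1.222,1.742
diepholz,CT2,1.22,5.62,0.55,0.080,0.031,0.037,0.021,0.021,0.424,0.988,1.703
diepholz,AS,1.26,5.99,0.55,0.100,0.038,0.024,0.026,0.018,0.628,1.222,0.813
diepholz,CM,0.92,5.70,0.18,0.080,0.031,0.028,0.021,0.018,0.424,0.988,0.854
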
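region,category,scenario,production_and_transport,feed_purchase,forage_production,enteric,in_house,outside_storage,total
oder_spree,GWP,Ref,0.000,0.149,0.166,0.465,0.100,0.134,1.014
oder_spree,GWP,SW_low,0.036,0.149,0.166,0.329,0.100,0.134,0.914
oder_spree,GWP,SW_high,0.071,0.149,0.166,0.161,0.100,0.134,0.781
oder_spree,GWP,CT1,0.003,0.149,0.166,0.465,0.100,0.134,1.018
oder_spree,GWP,CT2,0.003,0.149,0.157,0.465,0.100,0.104,0.978
oder_spree,GWP,AS,0.000,0.149,0.167,0.465,0.100,0.134,1.014
oder_spree,GWP,CM,0.075,0.149,0.159,0.161,0.100,0.104,0.748
oder_spree,EP,Ref,0.000,1.545,0.854,0.000,0.992,1.095,4.486
oder_spree,EP,SW_low,0.087,1.545,0.854,0.000,0.992,1.095,4.573
oder_spree,EP,SW_high,0.173,1.545,0.854,0.000,0.992,1.095,4.659
oder_spree,EP,CT1,0.007,1.545,0.854,0.000,0.788,1.095,4.289
oder_spree,EP,CT2,0.007,1.545,0.839,0.000,0.788,0.851,4.029
oder_spree,EP,AS,0.000,1.545,0.762,0.000,0.992,1.095,4.394
oder_spree,EP,CM,0.180,1.545,0.748,0.000,0.788,0.851,4.112
oder_spree,AP,Ref,0.000,0.883,0.462,0.000,2.864,4.747,8.956
oder_spree,AP,SW_low,0.230,0.883,0.462,0.000,2.864,4.747,9.186
oder_spree,AP,SW_high,0.460,0.883,0.462,0.000,2.864,4.747,9.416
oder_spree,AP,CT1,0.011,0.883,0.462,0.000,1.931,4.747,8.035
oder_spree,AP,CT2,0.011,0.883,0.385,0.000,1.931,3.687,6.897
oder_spree,AP,AS,0.001,0.883,0.538,0.000,2.864,4.747,9.033
oder_spree,AP,CM,0.471,0.883,0.450,0.000,1.931,3.687,7.422
oder_spree,AD,Ref,0.000,1.127,1.768,0.000,1.135,0.005,4.035
oder_spree,AD,SW_low,0.412,1.127,1.768,0.000,1.135,0.005,4.447
oder_spree,AD,SW_high,0.824,1.127,1.768,0.000,1.135,0.005,4.858
oder_spree,AD,CT1,0.031,1.127,1.768,0.000,1.135,0.005,4.066
oder_spree,AD,CT2,0.031,1.127,1.546,0.000,1.135,0.004,3.842
oder_spree,AD,AS,0.001,1.127,1.865,0.000,1.135,0.005,4.130
oder_spree,AD,CM,0.856,1.127,1.606,0.000,1.135,0.004,4.727
diepholz,GWP,Ref,0.000,0.262,0.162,0.548,0.128,0.159,1.259
diepholz,GWP,SW_low,0.038,0.262,0.162,0.375,0.128,0.159,1.124
diepholz,GWP,SW_high,0.076,0.262,0.162,0.178,0.128,0.159,0.965
diepholz,GWP,CT1,0.001,0.262,0.162,0.548,0.128,0.159,1.259
diepholz,GWP,CT2,0.001,0.262,0.152,0.548,0.128,0.129,1.219
diepholz,GWP,AS,0.001,0.262,0.159,0.548,0.128,0.159,1.256
diepholz,GWP,CM,0.078,0.262,0.146,0.178,0.128,0.129,0.919
diepholz,EP,Ref,0.000,2.749,0.881,0.000,1.169,1.290,6.089
diepholz,EP,SW_low,0.093,2.749,0.881,0.000,1.169,1.290,6.182
diepholz,EP,SW_high,0.186,2.749,0.881,0.000,1.169,1.290,6.275
diepholz,EP,CT1,0.001,2.749,0.881,0.000,0.966,1.290,5.886
diepholz,EP,CT2,0.001,2.749,0.865,0.000,0.966,1.042,5.623
diepholz,EP,AS,0.001,2.749,0.780,0.000,1.169,1.290,5.988
diepholz,EP,CM,0.188,2.749,0.759,0.000,0.966,1.042,5.703
diepholz,AP,Ref,0.000,1.642,0.389,0.000,3.214,5.589,10.834
diepholz,AP,SW_low,0.247,1.642,0.389,0.000,3.214,5.589,11.081
diepholz,AP,SW_high,0.493,1.642,0.389,0.000,3.214,5.589,11.327
diepholz,AP,CT1,0.002,1.642,0.389,0.000,2.282,5.589,9.904
diepholz,AP,CT2,0.002,1.642,0.311,0.000,2.282,4.515,8.752
diepholz,AP,AS,0.005,1.642,0.491,0.000,3.214,5.589,10.936
diepholz,AP,CM,0.501,1.642,0.398,0.000,2.282,4.515,9.332
diepholz,AD,Ref,0.000,2.033,1.367,0.000,1.447,0.006,4.852
diepholz,AD,SW_low,0.440,2.033,1.367,0.000,1.447,0.006,5.292
diepholz,AD,SW_high,0.880,2.033,1.367,0.000,1.447,0.006,5.732
diepholz,AD,CT1,0.006,2.033,1.367,0.000,1.447,0.006,4.858
diepholz,AD,CT2,0.006,2.033,1.166,0.000,1.447,0.005,4.656
diepholz,AD,AS,0.007,2.033,1.492,0.000,1.447,0.006,4.977
diepholz,AD,CM,0.893,2.033,1.258,0.000,1.447,0.005,5.628
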
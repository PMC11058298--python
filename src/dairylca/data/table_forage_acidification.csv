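region,category,ref_forage,as_forage,change_pct,share_production_transport_pct
oder_spree,GWP,0.166,0.167,0.1,0.05
oder_spree,EP,0.854,0.762,-10.8,0.02
oder_spree,AP,0.462,0.538,16.6,0.12
oder_spree,AD,1.768,1.865,5.5,0.05
diepholz,GWP,0.162,0.159,-1.8,0.43
diepholz,EP,0.881,0.780,-11.5,0.19
diepholz,AP,0.389,0.491,26.1,1.10
diepholz,AD,1.367,1.492,9.1,0.48
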
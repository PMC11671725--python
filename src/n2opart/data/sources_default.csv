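process,sp_mean,sp_sd,o18_mean,o18_sd
bD,-1.90,2.8,19.20,1.65
fD,33.50,3.18,47.20,3.28
Ni,35.00,1.68,23.50,3.0
nD,-5.9,3.88,16.8,1.25
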
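trait,beta,beta_se,gamma_PN,gamma_MD,gamma_ML,gamma_se_PN,gamma_se_MD,gamma_se_ML
PN,0.008,0.084,0.137,0.005,-0.118,0.133,0.145,0.158
MD,-0.029,0.090,0.005,-0.365,0.214,0.145,0.185,0.156
ML,0.021,0.021,-0.118,0.214,-0.206,0.158,0.156,0.199
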
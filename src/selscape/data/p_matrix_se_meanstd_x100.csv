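trait,PN,MD,ML
PN,0.034,0.026,0.075
MD,0.026,0.048,0.096
ML,0.075,0.096,0.340
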
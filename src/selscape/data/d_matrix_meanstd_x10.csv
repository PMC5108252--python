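trait,PN,MD,ML
PN,0.335,0.036,-0.017
MD,0.036,0.100,0.026
ML,-0.017,0.026,0.236
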
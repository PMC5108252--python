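trait,PN,MD,ML
PN,0.243,0.016,-0.063
MD,0.016,0.265,0.421
ML,-0.063,0.421,2.717
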
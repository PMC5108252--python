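trait,PN,MD,ML
PN,0.308,-0.007,-0.033
MD,-0.007,0.095,0.045
ML,-0.033,0.045,0.334
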
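axis,theta,lambda,PN,MD,ML
m1,0.004,0.181,0.926,-0.131,-0.354
m2,0.001,-0.094,0.361,0.581,0.729
m3,0.037,-0.522,0.111,-0.803,0.585
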
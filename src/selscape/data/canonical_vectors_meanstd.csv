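axis,PN,MD,ML
m_max,0.128,-0.686,0.716
m2,0.922,-0.184,-0.341
m1,0.365,0.704,0.609
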
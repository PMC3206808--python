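# source=columns
state,A,B,C,D,E,F
A,124,5,0,23,0,0
B,6,2,1,0,0,0
C,0,1,3,0,0,0
D,12,0,0,119,3,12
E,0,0,0,2,0,0
F,0,0,0,10,0,51
Total,142,8,4,154,3,63
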
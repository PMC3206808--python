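# source=columns
state,A,B,C,D,E,F
A,28,9,0,11,3,2
B,13,6,4,0,1,0
C,2,0,1,0,0,0
D,2,0,0,11,2,1
E,0,0,0,2,0,0
F,0,0,0,2,0,0
Total,45,15,5,26,6,3
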
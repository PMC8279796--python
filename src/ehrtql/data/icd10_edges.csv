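child,parent
E11.9,E11
E11.65,E11
E10.9,E10
I63.9,I63
I10,I10-I16
J20.9,J20
J44.9,J44
N18.3,N18
C50.911,C50.91
C50.91,C50
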
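child,parent
N02BE,N02B
N02B,N02
N02,N
A10BB,A10B
A10B,A10
A10,A
J01CA,J01C
J01C,J01
J01,J
J01FA,J01F
J01F,J01
C09AA,C09A
C09A,C09
C09,C
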
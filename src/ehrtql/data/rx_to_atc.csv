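rxcui,atc
161,N02BE
310490,A10BB
723,J01CA
641,J01FA
18631,J01FA
10829,J01CA
2193,J01CA
29046,C09AA
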
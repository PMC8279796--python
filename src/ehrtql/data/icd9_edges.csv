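child,parent
250.00,250.0
250.01,250.0
250.02,250.0
250.03,250.0
250.0,250
434.91,434.9
434.9,434
466.0,466
466.11,466.1
466.1,466
233.0,233
174.9,174
153.9,153
155.0,155
162.9,162
491.21,491.2
491.2,491
492.8,492
493.20,493.2
493.2,493
496,490-496
277.00,277.0
277.0,277
011.9,011
003.0,003
382.9,382
682.9,682
486,480-486
482.9,482
401.9,401
401.1,401
780.60,780.6
780.6,780
724.2,724
285.9,285
599.0,599
278.00,278.0
278.0,278
V72.31,V72.3
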
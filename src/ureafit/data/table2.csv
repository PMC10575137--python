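test_id,ca_mM,cb_mM,ph,ef_nA
10,0.5,0.05,5.5,1.17
11,1,0.05,5.5,1.07
12,0.5,0.1,5.5,0.93
13,1.5,0.1,5.5,0.73
14,1,0.25,5.5,0.93
15,1.5,0.25,5.5,0.8
16,0.5,0.25,6,0.86
17,1.5,0.25,6,0.67
18,0.5,0.1,6,0.78
19,1,0.1,6,0.71
20,1,0.05,6,0.9
21,1.5,0.05,6,0.77
22,0.5,0.25,6.5,1
23,1,0.25,6.5,0.91
24,1,0.1,6.5,0.82
25,1.5,0.1,6.5,0.71
26,0.5,0.05,6.5,1.14
27,1.5,0.05,6.5,0.89
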
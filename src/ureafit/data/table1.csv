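test_id,ca_mM,cb_mM,ph,ef_nA
1,0.5,0.25,5.5,0.67
2,1,0.1,5.5,0.87
3,1.5,0.05,5.5,0.9
4,1,0.25,6,0.775
5,1.5,0.1,6,0.775
6,0.5,0.05,6,1.05
7,1.5,0.25,6.5,0.85
8,0.5,0.1,6.5,0.82
9,1,0.05,6.5,1.175
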
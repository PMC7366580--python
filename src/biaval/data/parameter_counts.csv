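drug_id,n_population,n_market_share,n_dosage,n_acquisition_cost
A,4,5,4,1
B,7,5,1,1
C,15,30,1,2
D,14,10,1,1
E,3,12,2,1
F,91,5,2,3
G,21,15,1,1
H,5,5,1,1
I,10,5,1,1
J,8,5,2,1
K,5,5,1,1
L,4,5,1,1
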
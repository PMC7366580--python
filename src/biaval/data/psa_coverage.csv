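drug_id,year,status
A,1,inside_psa_bounds
A,2,inside_psa_bounds
B,1,inside_psa_bounds
B,2,outside_psa_bounds
B,3,outside_psa_bounds
C,1,outside_psa_bounds
C,2,inside_psa_bounds
C,3,inside_psa_bounds
D,1,outside_psa_bounds
D,2,outside_psa_bounds
E,1,outside_psa_bounds
E,2,outside_psa_bounds
E,3,outside_psa_bounds
F,1,outside_psa_bounds
F,2,outside_psa_bounds
F,3,outside_psa_bounds
F,4,outside_psa_bounds
F,5,outside_psa_bounds
G,1,inside_psa_bounds
G,2,inside_psa_bounds
G,3,inside_psa_bounds
G,4,outside_psa_bounds
H,1,inside_psa_bounds
H,2,outside_psa_bounds
H,3,outside_psa_bounds
H,4,outside_psa_bounds
I,1,inside_psa_bounds
I,2,inside_psa_bounds
I,3,inside_psa_bounds
J,1,outside_psa_bounds
J,2,outside_psa_bounds
K,1,outside_psa_bounds
K,2,inside_psa_bounds
L,1,inside_psa_bounds
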
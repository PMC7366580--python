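drug_id,year,error_pct
A,1,-36
A,2,-57
B,1,-49
B,2,-78
B,3,-94
C,1,420
C,2,22
C,3,-21
D,1,180
D,2,409
E,1,490
E,2,537
E,3,477
F,1,1017
F,2,585
F,3,334
F,4,219
F,5,165
G,1,6
G,2,-25
G,3,-56
G,4,-61
H,1,-49
H,2,-66
H,3,-87
I,1,72
I,2,79
I,3,228
J,1,-76
J,2,-72
K,1,95
K,2,59
L,1,-12
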
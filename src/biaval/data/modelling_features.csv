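drug_id,incidence,prevalence,population_growth,adherence,discontinuation,duration_of_treatment
A,False,True,True,False,False,False
B,False,True,True,False,False,False
C,False,True,True,True,False,False
D,True,True,False,False,True,False
E,True,True,False,False,False,True
F,False,True,True,False,False,False
G,False,True,True,False,False,False
H,True,True,False,False,False,True
I,True,True,True,False,True,False
J,True,True,True,False,False,True
K,False,True,True,False,False,False
L,True,True,False,False,False,False
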
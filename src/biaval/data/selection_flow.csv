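stage,n
identified,113
no_bim,21
multiple_indications,37
not_reimbursed_full_year,28
hospital_only,10
hepatitis_c,5
included,12
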
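cohort,n_GG,n_GT,n_TT
leukemia_patients,210,18,0
healthy_donors,185,40,1
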
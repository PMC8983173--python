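cohort,n_G,n_T
leukemia_patients,437,19
healthy_donors,410,42
lymphocytic_leukemia,108,4
myeloid_leukemia,294,14
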
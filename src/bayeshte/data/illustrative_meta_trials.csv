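study,e_int,n_int,e_ctl,n_ctl
illustrative_trial_A,25,216,44,218
illustrative_trial_B,44,99,30,102
illustrative_trial_C,78,484,68,481
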
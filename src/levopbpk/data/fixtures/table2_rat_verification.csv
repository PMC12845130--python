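metric,observed,simulated,ci90_low,ci90_high,ratio
auc_plasma_total_0_t,10.58,11.68,11.25,12.12,1.10
auc_plasma_total_0_inf,12.18,13.10,12.49,13.72,1.08
auc_lung_free_0_t,5.49,6.08,5.91,6.26,1.11
auc_lung_free_0_inf,5.78,6.60,6.38,6.83,1.14
auc_prostate_free_0_t,4.68,5.56,5.39,5.74,1.19
auc_prostate_free_0_inf,5.39,6.05,5.82,6.29,1.12
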
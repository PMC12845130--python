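metric,observed,simulated,ci90_low,ci90_high,ratio
auc_plasma_total_0_t,35.74,39.54,38.46,40.62,1.11
auc_plasma_total_0_inf,36.58,40.08,38.93,41.23,1.10
auc_lung_free_0_t,20.38,14.90,14.52,15.27,0.73
auc_lung_free_0_inf,36.34,23.35,22.69,24.01,0.65
auc_prostate_total_0_t,160.96,185.89,179.75,192.02,1.15
auc_prostate_total_0_inf,211.61,202.88,195.14,210.65,0.96
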
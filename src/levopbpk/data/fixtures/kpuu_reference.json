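{
  "regimen": "500 mg q24h, last dose",
  "auc_free_0_inf_ug_h_per_mL": {"plasma": 35.16, "lung": 27.74, "prostate": 25.15},
  "kpuu": {"lung": 0.79, "prostate": 0.72}
}
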
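{
  "name": "levofloxacin",
  "mw_g_per_mol": 361.4,
  "logd_74": -1.35,
  "pka1": 5.7,
  "pka2": 7.9,
  "solubility_ref_mg_per_L": 272.0,
  "diffusion_coeff_cm_per_s2": 7.5e-06,
  "fu_plasma": {"rat": 0.55, "human": 0.70},
  "rbp": {"rat": 0.9, "human": 1.0},
  "cl_renal_L_per_h": {"rat": 0.160, "human": 5.179},
  "cl_hepatic_L_per_h": {"rat": 0.0, "human": 1.300},
  "kp": {
    "lung": {"rat": 4.84, "human": 4.38},
    "prostate": {"rat": 5.0, "human": 5.0}
  },
  "fut": {
    "lung": {"rat": 0.100, "human": 0.141},
    "prostate": {"rat": 0.080, "human": 0.123}
  }
}
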
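{
  "tissue": "prostate",
  "target": 30.0,
  "window_h": [96.0, 120.0],
  "window_auc_ug_h_per_mL": {"500": 23.4, "750": 35.4, "1000": 45.7, "1250": 58.0},
  "breakpoints_mg_L": {
    "P. aeruginosa": 1.0,
    "S. pneumoniae": 2.0,
    "S. aureus": 1.0,
    "H. influenzae": 2.0,
    "Enterobacteriaceae": 0.5
  },
  "cells": {
    "P. aeruginosa":      {"500": 23.4, "750": 35.4, "1000": 45.7, "1250": 58.0},
    "S. pneumoniae":      {"500": 11.7, "750": 17.7, "1000": 22.9, "1250": 29.0},
    "S. aureus":          {"500": 23.4, "750": 35.4, "1000": 45.7, "1250": 58.0},
    "H. influenzae":      {"500": 11.7, "750": 17.7, "1000": 22.9, "1250": 29.0},
    "Enterobacteriaceae": {"500": 46.8, "750": 70.8, "1000": null, "1250": null}
  },
  "nc": [["Enterobacteriaceae", "1000"], ["Enterobacteriaceae", "1250"]]
}
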
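{
  "tissue": "lung",
  "target": 30.0,
  "window_h": [96.0, 120.0],
  "window_auc_ug_h_per_mL": {"500": 25.9, "750": 38.3, "1000": 49.5, "1250": 62.6},
  "breakpoints_mg_L": {
    "P. aeruginosa": 1.0,
    "S. pneumoniae": 2.0,
    "S. aureus": 1.0,
    "H. influenzae": 2.0,
    "Enterobacteriaceae": 0.5
  },
  "cells": {
    "P. aeruginosa":      {"500": 25.9, "750": 38.3, "1000": 49.5, "1250": 62.6},
    "S. pneumoniae":      {"500": 13.0, "750": 19.2, "1000": 24.8, "1250": 31.3},
    "S. aureus":          {"500": 25.9, "750": 38.3, "1000": 49.5, "1250": 62.6},
    "H. influenzae":      {"500": 13.0, "750": 19.2, "1000": 24.8, "1250": 31.3},
    "Enterobacteriaceae": {"500": 51.8, "750": 76.6, "1000": null, "1250": null}
  },
  "nc": [["Enterobacteriaceae", "1000"], ["Enterobacteriaceae", "1250"]]
}
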
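{
  "source": "published translational PBPK analysis of levofloxacin lung and prostate distribution",
  "fixtures": {
    "table1_compound": {
      "file": "table1_compound.json",
      "description": "Key physicochemical and biopharmaceutical parameters for levofloxacin (drug-specific model inputs)."
    },
    "table2_rat_verification": {
      "file": "table2_rat_verification.csv",
      "description": "Rat model verification: observed vs simulated AUC summaries (total plasma, free lung, free prostate) after a 7 mg/kg IV bolus. The source prints the final row's label as '0-t' twice; it is stored here as the 0-inf row, the only reading consistent with the other blocks."
    },
    "table3_human_verification": {
      "file": "table3_human_verification.csv",
      "description": "Human model verification: observed vs simulated AUC summaries (total plasma, free lung, total prostate) after 500 mg as a 1 h IV infusion."
    },
    "table4_lung_attainment": {
      "file": "table4_lung_attainment.json",
      "description": "Lung fAUC/MIC attainment grid: steady-state free lung AUC (96-120 h window) per regimen, CLSI susceptible breakpoints, and the published ratio cells (NC = not calculated)."
    },
    "table5_prostate_attainment": {
      "file": "table5_prostate_attainment.json",
      "description": "Prostate fAUC/MIC attainment grid, same structure as the lung table."
    },
    "kpuu_reference": {
      "file": "kpuu_reference.json",
      "description": "Reference unbound AUC0-inf values for the last 500 mg q24h dose (plasma, lung, prostate) and the Kp,uu ratios derived from them."
    }
  }
}
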
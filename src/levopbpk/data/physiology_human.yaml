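# Human (70 kg adult male) reference physiology; same simplified parallel
# topology as the rat file. Sources: Davies & Morris 1993; ICRP 89.
#
# gfr_L_per_h_per_kg back-calculated so fu * GFR reproduces the reference
# renal clearance of levofloxacin in humans (0.70 x 7.3986 L/h = 5.179 L/h
# at 70 kg) — a calibration constant, not a physiology claim.
species: human
citation: Davies & Morris 1993 (Pharm Res); ICRP Publication 89
cardiac_output_L_per_h_per_kg: 4.8
gfr_L_per_h_per_kg: 0.105694
tissues:
  - {name: venous_blood,  role: venous_pool,   volume_frac_bw: 0.0495, flow_frac_co: 0.0}
  - {name: arterial_blood, role: arterial_pool, volume_frac_bw: 0.0248, flow_frac_co: 0.0}
  - {name: lung,          role: lung_series,   volume_frac_bw: 0.0076, flow_frac_co: 1.0}
  - {name: adipose,       role: parallel,      volume_frac_bw: 0.2100, flow_frac_co: 0.050}
  - {name: bone,          role: parallel,      volume_frac_bw: 0.0860, flow_frac_co: 0.050}
  - {name: brain,         role: parallel,      volume_frac_bw: 0.0200, flow_frac_co: 0.120}
  - {name: gut,           role: parallel,      volume_frac_bw: 0.0171, flow_frac_co: 0.150}
  - {name: heart,         role: parallel,      volume_frac_bw: 0.0047, flow_frac_co: 0.040}
  - {name: kidney,        role: eliminating_renal,   volume_frac_bw: 0.0044, flow_frac_co: 0.190}
  - {name: liver,         role: eliminating_hepatic, volume_frac_bw: 0.0257, flow_frac_co: 0.065}
  - {name: muscle,        role: parallel,      volume_frac_bw: 0.4000, flow_frac_co: 0.170}
  - {name: skin,          role: parallel,      volume_frac_bw: 0.0371, flow_frac_co: 0.050}
  - {name: spleen,        role: parallel,      volume_frac_bw: 0.0026, flow_frac_co: 0.020}
  - {name: reproductive,  role: parallel,      volume_frac_bw: 0.0005, flow_frac_co: 0.005}
  - {name: rest,          role: parallel,      volume_frac_bw: 0.1100, flow_frac_co: 0.090}
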
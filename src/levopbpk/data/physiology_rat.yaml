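# Rat reference physiology for the whole-body perfusion-limited model.
# Organ volume fractions (of body weight, density ~1 g/mL) and regional
# blood-flow fractions (of cardiac output) compiled from the standard
# laboratory-animal compilations (Brown et al. 1997; Davies & Morris 1993),
# simplified to a parallel topology (no portal sub-circuit: gut and liver
# drain independently to the venous pool).
#
# gfr_L_per_h_per_kg is a calibration constant, not a physiology claim: it is
# back-calculated so that fu * GFR reproduces the reference renal clearance of
# levofloxacin in the rat (0.55 x 0.29091 L/h = 0.160 L/h at 0.3 kg).
species: rat
citation: Brown et al. 1997 (Toxicol Ind Health); Davies & Morris 1993 (Pharm Res)
cardiac_output_L_per_h_per_kg: 14.1   # unanesthetized; anesthesia lowers this
gfr_L_per_h_per_kg: 0.969697
tissues:
  - {name: venous_blood,  role: venous_pool,   volume_frac_bw: 0.0494, flow_frac_co: 0.0}
  - {name: arterial_blood, role: arterial_pool, volume_frac_bw: 0.0247, flow_frac_co: 0.0}
  - {name: lung,          role: lung_series,   volume_frac_bw: 0.0050, flow_frac_co: 1.0}
  - {name: adipose,       role: parallel,      volume_frac_bw: 0.0760, flow_frac_co: 0.070}
  - {name: bone,          role: parallel,      volume_frac_bw: 0.0415, flow_frac_co: 0.122}
  - {name: brain,         role: parallel,      volume_frac_bw: 0.0057, flow_frac_co: 0.020}
  - {name: gut,           role: parallel,      volume_frac_bw: 0.0270, flow_frac_co: 0.131}
  - {name: heart,         role: parallel,      volume_frac_bw: 0.0033, flow_frac_co: 0.049}
  - {name: kidney,        role: eliminating_renal,   volume_frac_bw: 0.0073, flow_frac_co: 0.141}
  - {name: liver,         role: eliminating_hepatic, volume_frac_bw: 0.0366, flow_frac_co: 0.021}
  - {name: muscle,        role: parallel,      volume_frac_bw: 0.4040, flow_frac_co: 0.278}
  - {name: skin,          role: parallel,      volume_frac_bw: 0.1900, flow_frac_co: 0.058}
  - {name: spleen,        role: parallel,      volume_frac_bw: 0.0020, flow_frac_co: 0.010}
  - {name: reproductive,  role: parallel,      volume_frac_bw: 0.0246, flow_frac_co: 0.011}
  - {name: rest,          role: parallel,      volume_frac_bw: 0.1029, flow_frac_co: 0.089}
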
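# Methods

## Model structure

The engine integrates a whole-body perfusion-limited system. State variables
are blood-pool concentrations (venous, arterial) and tissue *total*
concentrations; the lung carries the full cardiac output in series between
the pools, all other organs are perfused in parallel from the arterial pool.
For tissue *t* with flow `Q_t`, volume `V_t` and partition coefficient
`Kp_t`:

    V_t dC_t/dt = Q_t (C_art − C_t / Kp_b,t) [− CL · C_art / Rbp]

where `Kp_b = Kp / Rbp` references partitioning to blood and the bracketed
clearance term applies only to kidney (renal CL) and liver (hepatic CL).
Plasma concentration is blood concentration divided by Rbp, reported at the
venous sampling site. Clearances act on the *inflowing* arterial plasma
concentration, which keeps total plasma clearance equal to the configured
values for this low-extraction drug; model assembly rejects any clearance
exceeding its organ's perfusion limit (`CL ≤ Q·Rbp`). IV boluses enter the
venous pool as state jumps, infusions as zero-order rates, and integration
restarts at every dose boundary (LSODA, rtol 1e-8, atol 1e-10). Mass balance
(amount in body + eliminated = administered) holds below 1e-6 relative at
every output time, and the system reduces exactly to the textbook one- and
two-compartment solutions when all but one or two volumes are shrunk — both
are regression-tested.

Key identities used as oracles: plasma AUC0-inf = Dose/CL_total for any IV
regimen; C_t/C_plasma = Kp at constant-rate steady state; and over a full
dosing interval at the periodic steady state, the unbound AUC ratio
fAUC_tissue/fAUC_plasma equals `fut·Kp/fu` for any non-eliminating tissue
(`analytic_kpuu`).

## Parameters and calibrations

Drug-specific inputs (per species) ship in
`src/levopbpk/data/compound_levofloxacin.yaml`: fu 0.55/0.70 (rat/human),
Rbp 0.9/1.0, renal CL 0.160/5.179 L/h (= fu·GFR), hepatic CL 0/1.300 L/h,
Kp lung 4.84/4.38, Kp prostate 5.0 (assumed species-invariant), fut lung
0.100/0.141, fut prostate 0.080/0.123. Physicochemical fields (logD, pKa,
solubility, diffusion coefficient) are metadata only. Several quantities are
declared *calibrations*, not physiology claims:

* **GFR** is back-calculated so fu·GFR reproduces the reference renal
  clearances (rat 0.291 L/h at 0.3 kg; human 7.399 L/h at 70 kg).
* **Rat body weight** defaults to 0.3 kg, fixed by the reported Vss pair
  0.66 L = 2.2 L/kg.
* **Non-target tissue Kp**: only lung and prostate have measured values.
  All other distributing tissues share a single Kp solved in closed form so
  that `Vss = V_blood + Σ (Kp_t/Rbp)·V_t` matches the reported 2.2 L/kg
  (rat) and 1.6457 L/kg (human). Their fut is set to fu/Kp, the purely
  passive convention (Kp,uu = 1), so only lung/prostate unbound outputs
  carry scientific content.
* **Human total clearance**: the reported human plasma AUC0-inf for 500 mg
  (40.08 µg·h/mL) implies a total clearance of ~12.5 L/h, nearly twice the
  sum of the printed renal and hepatic values (6.48 L/h) — renal secretion
  beyond filtration is the likely physiologic reason. The default human
  model therefore scales both clearances by one factor
  (500/40.08)/6.479 ≈ 1.93 so simulated plasma exposure matches the
  verified clinical value; `human_model(calibrate_clearance=False)` gives
  the raw printed clearances. The relative renal/hepatic split is
  preserved. This discrepancy is flagged, not resolved; absolute human AUCs
  are accordingly judged by the two-fold verification gate rather than
  numeric equality.

The anesthesia operation rescales cardiac output to a per-kg target
(4.4 L/h/kg for anesthetized rats; the unanesthetized default is
14.1 L/h/kg) with all regional flows scaled proportionally. The prostate
carve-out splits the reproductive organ at conserved total volume and flow,
assigning the prostate flow in proportion to its volume fraction (the
"unchanged perfusion per volume" reading of an otherwise unspecified
rebalancing rule). Reference organ volumes and flow fractions are packaged
YAML compiled from the standard laboratory-animal/human compilations, with a
simplified parallel topology (no portal sub-circuit); they can be replaced
without code changes.

## Exposure metrics and reporting conventions

Non-compartmental metrics use the linear trapezoid (on dense simulated grids
the linear-up/log-down variant differs by <0.1%), a log-linear terminal
slope over a caller-chosen number of tail points (with a quality warning
when r² < 0.99 or the fitted stretch spans under two estimated half-lives),
and `AUC0-inf = AUC0-t + C_last/λz`. Two numerical points deserve note:

* A venous IV bolus produces a mixing transient decaying at ~CO/V_venous per
  hour; trapezoidal integration on the default 0.05 h grid overestimates its
  area (~17% for the rat). `engine.refined_grid` adds millisecond-scale
  resolution after each bolus so trapezoidal AUCs converge to the true
  integral (Dose/CL to <0.1%).
* The rat terminal slope is 0.217 /h, about 11% below the one-compartment
  limit CL/Vss = 0.242 /h, because peripheral distribution (slowly
  equilibrating small tissues) flattens the terminal phase. Tests gate the
  slope at 15% of the limit for this reason.

Reported ratios follow the published conventions: fAUC/MIC to one decimal
and Kp,uu / PRED-OBS ratios to two, all rounded half-up (half-up, not
half-even, reproduces every printed attainment cell, e.g. 45.7/2 → 22.9).
The attainment threshold is inclusive (≥ 30). Cells for Enterobacteriaceae
at the two hypothetical high doses are flagged "not calculated" to mirror
the published tables; a config switch computes them anyway. The assumed
observed 0-t horizon for the rat verification metrics is 8 h (the source
horizons are not stated).

## Kp estimation

`fit_kp` recovers a single tissue's Kp from unbound tissue observations by
bounded scalar minimization (Kp ∈ [0.1, 50], deterministic) of a sum of
squared residuals, log-scale by default — proportional error is appropriate
for concentrations spanning a decay — with an additive option. This is the
mechanism by which prostate efflux is absorbed into a lower effective Kp
instead of an explicit transporter model (a permeability-limited Vmax/Km
description is out of scope). The objective has no free intercept, so Kp is
identified by both the level and the equilibration kinetics of the tissue
profile; rescaling observations *alone* is therefore not a symmetry of the
fit, but rescaling dose and observations together is (unit consistency),
and that is the tested invariance. On the synthetic study design (12 samples
over 0.5–8 h post-bolus, 15% proportional noise, 20 seeds) the recovered
prostate Kp stays within 15% of truth, and within 1% on noise-free data.

## Synthetic data and the population layer

`generate_observations` emulates the *structure* of the source studies —
sparse schedules, unbound-tissue (microdialysis) vs total-plasma matrices,
multiplicative log-normal noise with median 1, censoring below a 0.01 µg/mL
LLOQ — from the model's own truth profiles. It does not emulate probe
recovery/retrodialysis calibration (assumed pre-corrected), between-animal
physiology differences beyond the population layer, or assay-specific error
shapes; passing recovery tests therefore demonstrates estimator correctness
under the stated error model, not performance on any real dataset.

`population_simulate` perturbs clearance, every Kp entry and cardiac output
log-normally (median-preserving) with per-subject substreams spawned from a
single root seed; identical seeds give bit-identical bands. The default CVs
(CL 25%, Kp 20%, CO 15%) are assumptions typical of PBPK population
settings — the source population module's variances are not published — and
every report records the CVs and seed used. The "90% CI" columns of the
verification summaries are interpreted as the normal-approximation CI of
the mean across subjects (configurable to a percentile interval).

## Problem sizes and defaults

Default output step 0.05 h; clinical steady state reached with five q24h
doses (the fifth interval, 96–120 h, is periodic to <0.5%); rat bolus
simulations run 48 h; the recovery and population studies use 20 seeds × 12
samples and 100 subjects respectively. These sizes were chosen so each
analysis completes in seconds while keeping discretization error well below
the assertion tolerances.

## Known limitations

No oral absorption (clinical regimens are simulated as 1-h IV infusions;
with near-complete bioavailability the AUC-level exposure is equivalent);
no permeability-limited or transporter-explicit compartments; no
disease-state physiology (infection can reduce fluoroquinolone penetration
substantially, so healthy-tissue attainment is optimistic for chronic
infection); MIC values are fixed CLSI breakpoints without distributional
uncertainty; the engine's own steady-state Kp,uu (fut·Kp/fu ≈ 0.88 for both
tissues) sits above the reported last-dose values (0.79 lung, 0.72
prostate), which derive from the source platform's internal unbound
calculation — the package reproduces those numbers as arithmetic on the
reported AUCs and does not force the engine to match them.
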
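"""Human dose adequacy: steady-state fAUC/MIC attainment in lung and prostate.

Simulates each q24h regimen (500-1250 mg, 1-h IV infusions) to the fifth
dosing interval (96-120 h), integrates the unbound tissue concentrations over
that interval, and crosses the free AUCs with CLSI susceptible breakpoints.
A ratio >= 30 predicts antibacterial efficacy for fluoroquinolones.
"""

import levopbpk as lp
from levopbpk.pkpd import BreakpointTable, build_attainment_table

model = lp.human_model()  # 70 kg, 21 mL prostate, clearance-calibrated
breakpoints = BreakpointTable.from_csv()
nc = {("Enterobacteriaceae", 1000), ("Enterobacteriaceae", 1250)}

window_auc = {"lung": {}, "prostate": {}}
for dose, regimen in lp.standard_regimens().items():
    result = lp.simulate(model, regimen, t_end=120.0)
    window = lp.steady_state_window(result, 96.0, 120.0)
    for tissue in ("lung", "prostate"):
        window_auc[tissue][dose] = lp.auc_trapezoid(
            window.times, window.unbound(tissue)
        )

# last-dose Kp,uu: unbound tissue over unbound plasma exposure
result = lp.simulate(model, lp.standard_regimens()[500], t_end=120.0)
window = lp.steady_state_window(result, 96.0, 120.0)
auc_plasma_u = lp.auc_trapezoid(window.times, window.plasma_unbound)
for tissue in ("lung", "prostate"):
    auc_t = lp.auc_trapezoid(window.times, window.unbound(tissue))
    print(f"Kp,uu {tissue:8s} {auc_t / auc_plasma_u:.2f} "
          f"(closed form fut*Kp/fu = "
          f"{lp.analytic_kpuu(model.partition.kp(tissue), model.partition.fut(tissue), 0.70):.2f})")

for tissue in ("lung", "prostate"):
    table = build_attainment_table(window_auc[tissue], breakpoints, nc_rules=nc)
    print(f"\n{table.report()}")
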
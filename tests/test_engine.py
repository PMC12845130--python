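import numpy as np
import pytest
from conftest import toy_model

import levopbpk as lp
from levopbpk.compound import CompoundParams
from levopbpk.engine import DoseEvent, build_model, refined_grid
from levopbpk.errors import (
    ConfigurationError,
    ValidationError,
    WindowRangeError,
)
from levopbpk.partition import PartitionEntry, PartitionSet


@pytest.mark.filterwarnings("ignore:terminal fit")
def test_degenerate_one_tissue_auc_is_dose_over_cl():
    """Whole body as a single cleared compartment: AUC0-inf = Dose / CL."""
    model = toy_model(v1=1.0, v2=None, qk=5.0, cl=0.5)
    dose = DoseEvent(route="iv_bolus", amount=10.0)
    res = lp.simulate(model, dose, t_end=20.0, t_eval=refined_grid(20.0, dose))
    s = lp.nca(res.times, res.plasma_total, n_terminal=50)
    assert s.auc_0_inf == pytest.approx(10.0 / 0.5, rel=5e-3)


def test_rat_bolus_auc_matches_clearance_identity(rat_bolus_result):
    s = lp.nca(rat_bolus_result.times, rat_bolus_result.plasma_total, n_terminal=200)
    assert s.auc_0_inf == pytest.approx(2.1 / 0.160, rel=5e-3)


def test_mass_balance(rat_bolus_result, human_500_result):
    assert rat_bolus_result.mass_balance_error() < 1e-6
    assert human_500_result.mass_balance_error() < 1e-6
    # eliminated amounts approach the administered dose
    assert rat_bolus_result.eliminated["renal"][-1] == pytest.approx(2.1, rel=1e-3)


def test_dose_linearity(rat_model):
    """Superposition: doubling the dose doubles every concentration."""
    r1 = lp.simulate(rat_model, lp.rat_bolus(), t_end=24.0, output_step=0.2)
    d2 = DoseEvent(route="iv_bolus", amount=2 * 2.1)
    r2 = lp.simulate(rat_model, d2, t_end=24.0, output_step=0.2)
    for name in r1.conc:
        np.testing.assert_allclose(2 * r1.conc[name], r2.conc[name], rtol=1e-6)


def test_constant_infusion_steady_state_kp(rat_model):
    """At constant-rate steady state C_tissue / C_plasma = Kp (non-eliminating)."""
    inf = DoseEvent(route="iv_infusion", amount=96.0, duration=96.0)
    res = lp.simulate(rat_model, inf, t_end=96.0, output_step=0.5)
    c_plasma = res.plasma_total[-1]
    for tissue in ("lung", "prostate", "muscle"):
        ratio = res.conc[tissue][-1] / c_plasma
        assert ratio == pytest.approx(rat_model.partition.kp(tissue), rel=1e-3)


def test_two_compartment_closed_form():
    """Reduced engine vs textbook bi-exponential bolus solution."""
    v1, v2, kp2, q2, cl = 3.0, 10.0, 4.0, 20.0, 2.0
    dose = 100.0
    model = toy_model(v1=v1, v2=v2, kp2=kp2, q2=q2, qk=5.0, cl=cl)
    t = np.arange(0.05, 24.0, 0.05)
    res = lp.simulate(model, DoseEvent(route="iv_bolus", amount=dose),
                      t_end=24.0, t_eval=t)
    k10, k12, k21 = cl / v1, q2 / v1, q2 / (kp2 * v2)
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4 * k10 * k21)
    alpha, beta = (s + disc) / 2, (s - disc) / 2
    c0 = dose / v1
    closed = c0 * (
        (alpha - k21) / (alpha - beta) * np.exp(-alpha * res.times)
        + (k21 - beta) / (alpha - beta) * np.exp(-beta * res.times)
    )
    np.testing.assert_allclose(res.plasma_total, closed, rtol=1e-3)


def test_steady_state_window_slice(human_500_result):
    win = lp.steady_state_window(human_500_result, 96.0, 120.0)
    assert win.times[0] == pytest.approx(96.0)
    assert win.times[-1] == pytest.approx(120.0)
    assert win.times[-1] - win.times[0] == pytest.approx(24.0)
    with pytest.raises(WindowRangeError):
        lp.steady_state_window(human_500_result, 50.0, 50.0)
    with pytest.raises(WindowRangeError):
        lp.steady_state_window(human_500_result, 110.0, 130.0)


def test_periodic_interval_auc(human_model):
    """At steady state every full dosing interval carries the same AUC."""
    res = lp.simulate(human_model, lp.infusion_regimen(500, n_doses=6), t_end=144.0)
    a = lp.steady_state_window(res, 96.0, 120.0)
    b = lp.steady_state_window(res, 120.0, 144.0)
    auc_a = lp.auc_trapezoid(a.times, a.plasma_total)
    auc_b = lp.auc_trapezoid(b.times, b.plasma_total)
    assert auc_b == pytest.approx(auc_a, rel=5e-3)


@pytest.mark.parametrize("tissue", ["lung", "prostate"])
def test_interval_kpuu_matches_closed_form(human_500_result, human_model, tissue):
    """Last-interval unbound AUC ratio equals fut*Kp/fu for passive tissues."""
    win = lp.steady_state_window(human_500_result, 96.0, 120.0)
    auc_tissue = lp.auc_trapezoid(win.times, win.unbound(tissue))
    auc_plasma = lp.auc_trapezoid(win.times, win.plasma_unbound)
    expected = lp.analytic_kpuu(
        human_model.partition.kp(tissue),
        human_model.partition.fut(tissue),
        human_model.compound.fu_plasma,
    )
    assert auc_tissue / auc_plasma == pytest.approx(expected, rel=5e-3)


def test_build_model_validation(rat_model):
    phys = rat_model.physiology
    with pytest.raises(ConfigurationError):
        build_model(
            phys,
            rat_model.compound,
            PartitionSet(species="rat", entries={"lung": PartitionEntry(4.84, 0.1)}),
        )
    too_fast = CompoundParams(
        name="x", species="rat", fu_plasma=0.55, rbp=0.9,
        cl_renal=10.0, cl_hepatic=0.0,  # exceeds kidney Q*Rbp
    )
    with pytest.raises(ConfigurationError):
        build_model(phys, too_fast, rat_model.partition)


def test_dose_event_and_simulate_validation(rat_model):
    with pytest.raises(ValidationError):
        DoseEvent(route="oral", amount=1.0)
    with pytest.raises(ValidationError):
        DoseEvent(route="iv_infusion", amount=1.0, duration=0.0)
    with pytest.raises(ValidationError):
        DoseEvent(route="iv_bolus", amount=-1.0)
    with pytest.raises(ValidationError):
        lp.simulate(rat_model, lp.infusion_regimen(500, n_doses=5), t_end=48.0)
    with pytest.raises(ValidationError):
        lp.simulate(rat_model, lp.rat_bolus(), t_end=10.0, t_eval=[3.0, 1.0])
    with pytest.raises(ValidationError):
        lp.simulate(rat_model, [], t_end=10.0)
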
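import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from levopbpk import apply_anesthesia, carve_prostate, load_physiology
from levopbpk.errors import (
    DuplicateCompartmentError,
    UnsupportedSpeciesError,
    ValidationError,
)
from levopbpk.physiology import PhysiologyTable


@pytest.mark.parametrize("species,bw", [("rat", 0.3), ("human", 70.0)])
def test_flow_balance_and_structure(species, bw):
    table = load_physiology(species, bw)
    q = sum(t.blood_flow for t in table.parallel_tissues)
    assert q == pytest.approx(table.cardiac_output, rel=1e-12)
    assert table.lung.role == "lung_series"
    assert table.lung.blood_flow == pytest.approx(table.cardiac_output)
    assert table.body_weight == bw


def test_gfr_matches_renal_clearance_backcalculation():
    """fu*GFR must reproduce the reference renal clearances of levofloxacin."""
    rat = load_physiology("rat", 0.3)
    assert 0.55 * rat.gfr == pytest.approx(0.160, rel=1e-3)
    assert rat.gfr == pytest.approx(0.291, abs=5e-4)
    human = load_physiology("human", 70.0)
    assert 0.70 * human.gfr == pytest.approx(5.179, rel=1e-3)


def test_unknown_species_rejected():
    with pytest.raises(UnsupportedSpeciesError):
        load_physiology("dog", 10.0)
    with pytest.raises(ValidationError):
        load_physiology("rat", -1.0)


def test_anesthesia_cardiac_output():
    """Anesthetized rat cardiac output: 4.4 L/h/kg -> 1.32 L/h at 0.3 kg."""
    table = apply_anesthesia(load_physiology("rat", 0.3), 4.4)
    assert table.cardiac_output == pytest.approx(1.32, rel=1e-12)
    ml_per_s = table.cardiac_output * 1000 / 3600
    assert ml_per_s == pytest.approx(0.367, abs=5e-4)
    q = sum(t.blood_flow for t in table.parallel_tissues)
    assert q == pytest.approx(table.cardiac_output, rel=1e-9)


def test_anesthesia_identity():
    table = load_physiology("rat", 0.3)
    same = apply_anesthesia(table, table.cardiac_output / table.body_weight)
    for a, b in zip(table.tissues, same.tissues):
        assert b.blood_flow == pytest.approx(a.blood_flow, rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(k=st.floats(min_value=0.05, max_value=20.0))
def test_anesthesia_homogeneous_in_co(k):
    """Scaling the target CO by k scales every regional flow by k."""
    base = load_physiology("rat", 0.25)
    co_per_kg = base.cardiac_output / base.body_weight
    scaled = apply_anesthesia(base, k * co_per_kg)
    for a, b in zip(base.parallel_tissues, scaled.parallel_tissues):
        assert b.blood_flow == pytest.approx(k * a.blood_flow, rel=1e-9)


@pytest.mark.parametrize(
    "species,bw,vol_L",
    [("rat", 0.3, 0.65e-3), ("human", 70.0, 21e-3)],
)
def test_carve_prostate_volume_and_balance(species, bw, vol_L):
    before = load_physiology(species, bw)
    repro_v = before.tissue("reproductive").volume
    repro_q = before.tissue("reproductive").blood_flow
    after = carve_prostate(before, vol_L)
    prostate = after.tissue("prostate")
    assert prostate.volume == pytest.approx(vol_L)
    # reproductive block conserved: volume split, total flow unchanged
    assert prostate.volume + after.tissue("reproductive").volume == pytest.approx(
        repro_v
    )
    assert prostate.blood_flow + after.tissue("reproductive").blood_flow == (
        pytest.approx(repro_q)
    )
    # perfusion per unit volume unchanged by the split
    assert prostate.blood_flow / prostate.volume == pytest.approx(
        repro_q / repro_v, rel=1e-12
    )
    q = sum(t.blood_flow for t in after.parallel_tissues)
    assert q == pytest.approx(after.cardiac_output, rel=1e-9)


def test_carve_prostate_errors():
    table = carve_prostate(load_physiology("rat", 0.3), 0.65e-3)
    with pytest.raises(DuplicateCompartmentError):
        carve_prostate(table, 0.65e-3)
    with pytest.raises(ValidationError):
        carve_prostate(load_physiology("rat", 0.3), 1.0)  # bigger than the organ


def test_serialization_round_trip(tmp_path):
    table = carve_prostate(load_physiology("human", 70.0), 21e-3)
    rebuilt = PhysiologyTable.from_dict(table.to_dict())
    assert rebuilt == table
    path = tmp_path / "phys.yaml"
    table.to_yaml(path)
    assert "prostate" in path.read_text()
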
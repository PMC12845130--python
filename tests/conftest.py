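import numpy as np
import pytest

import levopbpk as lp
from levopbpk.compound import CompoundParams
from levopbpk.engine import build_model, refined_grid
from levopbpk.partition import PartitionEntry, PartitionSet
from levopbpk.physiology import PhysiologyTable, TissueSpec


def toy_model(v1=3.0, v2=None, kp2=4.0, q2=None, qk=5.0, cl=2.0, rbp=1.0, v_small=1e-4):
    """Reducible test system: big venous pool, optional peripheral tissue,
    near-zero lung/arterial/kidney volumes so the engine collapses onto the
    textbook 1- or 2-compartment model."""
    tissues = [
        TissueSpec("venous_blood", v1, 0.0, "venous_pool"),
        TissueSpec("arterial_blood", v_small, 0.0, "arterial_pool"),
    ]
    co = qk + (q2 or 0.0)
    tissues.append(TissueSpec("lung", v_small, co, "lung_series"))
    entries = {"lung": PartitionEntry(kp=rbp, fut=1.0)}
    if v2 is not None:
        tissues.append(TissueSpec("body", v2, q2, "parallel"))
        entries["body"] = PartitionEntry(kp=kp2 * rbp, fut=1.0)
    tissues.append(TissueSpec("kidney", v_small, qk, "eliminating_renal"))
    entries["kidney"] = PartitionEntry(kp=rbp, fut=1.0)
    phys = PhysiologyTable(
        species="rat", body_weight=1.0, cardiac_output=co, gfr=0.0,
        tissues=tuple(tissues),
    )
    compound = CompoundParams(
        name="toy", species="rat", fu_plasma=1.0, rbp=rbp, cl_renal=cl,
        cl_hepatic=0.0,
    )
    return build_model(phys, compound, PartitionSet(species="rat", entries=entries))


@pytest.fixture(scope="session")
def rat_model():
    return lp.rat_model()


@pytest.fixture(scope="session")
def human_model():
    return lp.human_model()


@pytest.fixture(scope="session")
def rat_bolus_result(rat_model):
    """7 mg/kg IV bolus, 48 h, bolus-refined output grid."""
    regimen = lp.rat_bolus()
    grid = refined_grid(48.0, regimen)
    return lp.simulate(rat_model, regimen, t_end=48.0, t_eval=grid)


@pytest.fixture(scope="session")
def human_500_result(human_model):
    """500 mg q24h x 5 as 1-h infusions, 0-120 h."""
    return lp.simulate(human_model, lp.infusion_regimen(500), t_end=120.0)


@pytest.fixture(scope="session")
def recovery_schedule():
    """Sparse microdialysis emulation: 12 samples over 0.5-8 h post-bolus."""
    return list(np.round(np.linspace(0.5, 8.0, 12), 4))
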
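"""Species physiology: organ volumes, regional blood flows, cardiac output, GFR.

The whole-body model uses a standard perfusion-limited topology: a venous
pool collects the outflow of all parallel tissues, the lung sits in series
between the venous and arterial pools, and every other organ is perfused in
parallel from the arterial pool. Reference volumes and flow fractions ship as
versioned YAML data files (one per species) so they can be swapped without
code changes.

Two study-specific manipulations are provided as pure operations:

* :func:`apply_anesthesia` — rescales cardiac output (and every regional flow
  proportionally) to the depressed cardiac output of anesthetized animals.
* :func:`carve_prostate` — splits a prostate compartment out of the generic
  reproductive organ, preserving total volume and perfusion per unit volume.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

from .errors import (
    ConfigurationError,
    DuplicateCompartmentError,
    UnsupportedSpeciesError,
    ValidationError,
)

ROLES = frozenset(
    {
        "lung_series",
        "parallel",
        "eliminating_renal",
        "eliminating_hepatic",
        "venous_pool",
        "arterial_pool",
    }
)

#: roles whose blood flows must sum to cardiac output
PARALLEL_ROLES = frozenset({"parallel", "eliminating_renal", "eliminating_hepatic"})

FLOW_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class TissueSpec:
    """One compartment: a name, a volume [L], a blood flow [L/h] and a role."""

    name: str
    volume: float
    blood_flow: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown tissue role {self.role!r}")
        if self.volume <= 0:
            raise ValidationError(f"tissue {self.name!r}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValidationError(f"tissue {self.name!r}: blood_flow must be >= 0")


@dataclass(frozen=True)
class PhysiologyTable:
    """Species physiology scaled to a given body weight.

    Invariants (checked by :meth:`validate`): exactly one lung-series tissue,
    one venous and one arterial pool, and the parallel-tissue blood flows sum
    to cardiac output to within ``FLOW_BALANCE_RTOL`` relative.
    """

    species: str
    body_weight: float  # kg
    cardiac_output: float  # L/h
    gfr: float  # L/h
    tissues: tuple[TissueSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissues", tuple(self.tissues))
        self.validate()

    # -- queries ---------------------------------------------------------

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def has_tissue(self, name: str) -> bool:
        return any(t.name == name for t in self.tissues)

    @property
    def parallel_tissues(self) -> tuple[TissueSpec, ...]:
        return tuple(t for t in self.tissues if t.role in PARALLEL_ROLES)

    @property
    def lung(self) -> TissueSpec:
        return next(t for t in self.tissues if t.role == "lung_series")

    @property
    def venous(self) -> TissueSpec:
        return next(t for t in self.tissues if t.role == "venous_pool")

    @property
    def arterial(self) -> TissueSpec:
        return next(t for t in self.tissues if t.role == "arterial_pool")

    @property
    def blood_volume(self) -> float:
        return self.venous.volume + self.arterial.volume

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be > 0")
        for role in ("lung_series", "venous_pool", "arterial_pool"):
            if sum(1 for t in self.tissues if t.role == role) != 1:
                raise ConfigurationError(f"exactly one tissue must have role {role!r}")
        names = [t.name for t in self.tissues]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate tissue names")
        q = sum(t.blood_flow for t in self.parallel_tissues)
        if abs(q - self.cardiac_output) > FLOW_BALANCE_RTOL * self.cardiac_output:
            raise ConfigurationError(
                f"parallel flows ({q:.6g} L/h) do not sum to cardiac output "
                f"({self.cardiac_output:.6g} L/h)"
            )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "body_weight_kg": self.body_weight,
            "cardiac_output_L_per_h": self.cardiac_output,
            "gfr_L_per_h": self.gfr,
            "tissues": [
                {
                    "name": t.name,
                    "volume_L": t.volume,
                    "blood_flow_L_per_h": t.blood_flow,
                    "role": t.role,
                }
                for t in self.tissues
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhysiologyTable":
        return cls(
            species=d["species"],
            body_weight=float(d["body_weight_kg"]),
            cardiac_output=float(d["cardiac_output_L_per_h"]),
            gfr=float(d["gfr_L_per_h"]),
            tissues=tuple(
                TissueSpec(
                    name=t["name"],
                    volume=float(t["volume_L"]),
                    blood_flow=float(t["blood_flow_L_per_h"]),
                    role=t["role"],
                )
                for t in d["tissues"]
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _reference_data(species: str) -> dict:
    fname = f"physiology_{species}.yaml"
    pkg = importlib.resources.files("levopbpk.data")
    try:
        text = (pkg / fname).read_text()
    except FileNotFoundError:
        raise UnsupportedSpeciesError(
            f"no packaged physiology for species {species!r}"
        ) from None
    return yaml.safe_load(text)


def load_physiology(species: str, body_weight: float) -> PhysiologyTable:
    """Load the packaged reference physiology scaled to ``body_weight`` [kg].

    Volumes scale linearly with body weight; regional flows are the packaged
    fractions of a per-kg cardiac output (fractions are renormalized so the
    flow-balance invariant holds exactly).
    """
    if body_weight <= 0:
        raise ValidationError("body_weight must be > 0")
    ref = _reference_data(species)
    co = float(ref["cardiac_output_L_per_h_per_kg"]) * body_weight
    gfr = float(ref["gfr_L_per_h_per_kg"]) * body_weight
    rows = ref["tissues"]
    frac_sum = sum(
        float(r["flow_frac_co"]) for r in rows if r["role"] in PARALLEL_ROLES
    )
    tissues = []
    for r in rows:
        role = r["role"]
        if role == "lung_series":
            flow = co
        elif role in PARALLEL_ROLES:
            flow = co * float(r["flow_frac_co"]) / frac_sum
        else:
            flow = 0.0
        tissues.append(
            TissueSpec(
                name=r["name"],
                volume=float(r["volume_frac_bw"]) * body_weight,
                blood_flow=flow,
                role=role,
            )
        )
    return PhysiologyTable(
        species=ref["species"],
        body_weight=body_weight,
        cardiac_output=co,
        gfr=gfr,
        tissues=tuple(tissues),
    )


def apply_anesthesia(table: PhysiologyTable, co_per_kg: float) -> PhysiologyTable:
    """Rescale cardiac output to ``co_per_kg`` [L/h/kg] preserving flow fractions.

    All regional flows (and the lung series flow) scale by the same factor, so
    the fractional distribution of cardiac output is unchanged.
    """
    if co_per_kg <= 0:
        raise ValidationError("co_per_kg must be > 0")
    new_co = co_per_kg * table.body_weight
    k = new_co / table.cardiac_output
    tissues = tuple(
        replace(t, blood_flow=t.blood_flow * k) if t.blood_flow > 0 else t
        for t in table.tissues
    )
    return replace(table, cardiac_output=new_co, tissues=tissues)


def carve_prostate(table: PhysiologyTable, prostate_volume: float) -> PhysiologyTable:
    """Split a ``prostate`` compartment out of the ``reproductive`` tissue.

    The reproductive block's total volume and total blood flow are preserved;
    the prostate receives flow in proportion to its volume fraction of the
    original reproductive tissue (unchanged perfusion per unit volume).
    """
    if table.has_tissue("prostate"):
        raise DuplicateCompartmentError("prostate compartment already present")
    if not table.has_tissue("reproductive"):
        raise ConfigurationError("no reproductive tissue to carve the prostate from")
    repro = table.tissue("reproductive")
    if not 0 < prostate_volume < repro.volume:
        raise ValidationError(
            f"prostate volume must lie in (0, {repro.volume:.6g}) L, "
            f"got {prostate_volume:.6g}"
        )
    vfrac = prostate_volume / repro.volume
    prostate = TissueSpec(
        name="prostate",
        volume=prostate_volume,
        blood_flow=repro.blood_flow * vfrac,
        role="parallel",
    )
    shrunk = replace(
        repro,
        volume=repro.volume - prostate_volume,
        blood_flow=repro.blood_flow * (1.0 - vfrac),
    )
    tissues = []
    for t in table.tissues:
        if t.name == "reproductive":
            tissues.extend([shrunk, prostate])
        else:
            tissues.append(t)
    return replace(table, tissues=tuple(tissues))
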
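"""Drug-specific parameters and clearance arithmetic.

Renal clearance of levofloxacin is modeled as glomerular filtration of the
unbound fraction, ``CL_renal = fu * GFR``. In humans renal elimination is
~80% of the total, and the hepatic remainder follows from that split.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import DomainError, UnsupportedSpeciesError, ValidationError


@dataclass(frozen=True)
class CompoundParams:
    """Drug constants resolved for one species.

    ``logd_74``, ``pka_*``, ``solubility_ref`` and ``diffusion_coeff`` are
    metadata only — the perfusion-limited model consumes fu, Rbp and the two
    clearances, with tissue partitioning supplied separately.
    """

    name: str
    species: str
    fu_plasma: float  # fraction unbound in plasma
    rbp: float  # blood:plasma total-concentration ratio
    cl_renal: float  # L/h
    cl_hepatic: float  # L/h
    mw: Optional[float] = None  # g/mol
    logd_74: Optional[float] = None
    pka_acidic: Optional[float] = None
    pka_basic: Optional[float] = None
    solubility_ref: Optional[float] = None  # mg/L
    diffusion_coeff: Optional[float] = None  # cm/s^2 (metadata)

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise ValidationError("fu_plasma must be in (0, 1]")
        if self.rbp <= 0:
            raise ValidationError("rbp must be > 0")
        if self.cl_renal < 0 or self.cl_hepatic < 0:
            raise ValidationError("clearances must be >= 0")

    @property
    def cl_total(self) -> float:
        return self.cl_renal + self.cl_hepatic

    def scaled(self, factor: float) -> "CompoundParams":
        """Return a copy with both clearances multiplied by ``factor``."""
        if factor <= 0:
            raise ValidationError("clearance scale factor must be > 0")
        return CompoundParams(
            **{
                **self.__dict__,
                "cl_renal": self.cl_renal * factor,
                "cl_hepatic": self.cl_hepatic * factor,
            }
        )


def renal_clearance(fu_plasma: float, gfr: float) -> float:
    """CL_renal = fu * GFR [L/h] (filtration of the unbound fraction only)."""
    if not 0 <= fu_plasma <= 1:
        raise ValidationError("fu_plasma must be in [0, 1]")
    if gfr < 0:
        raise ValidationError("gfr must be >= 0")
    return fu_plasma * gfr


def hepatic_clearance_from_fraction(cl_renal: float, renal_fraction: float) -> float:
    """Hepatic clearance implied by renal CL being ``renal_fraction`` of total.

    ``CL_hep = CL_ren * (1 - f) / f``; e.g. 5.179 L/h renal at an 80% renal
    fraction implies ~1.3 L/h hepatic.
    """
    if not 0 < renal_fraction <= 1:
        raise DomainError("renal_fraction must be in (0, 1]")
    return cl_renal * (1.0 - renal_fraction) / renal_fraction


def load_compound_config(path=None) -> dict:
    """Load a compound config file (default: the packaged levofloxacin file)."""
    if path is None:
        pkg = importlib.resources.files("levopbpk.data")
        text = (pkg / "compound_levofloxacin.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def compound_from_config(cfg: dict, species: str) -> CompoundParams:
    """Resolve a :class:`CompoundParams` for one species from a config dict."""
    try:
        sp = cfg["species"][species]
    except KeyError:
        raise UnsupportedSpeciesError(
            f"compound config {cfg.get('name', '?')!r} has no entry for {species!r}"
        ) from None
    return CompoundParams(
        name=cfg["name"],
        species=species,
        fu_plasma=float(sp["fu_plasma"]),
        rbp=float(sp["rbp"]),
        cl_renal=float(sp["cl_renal_L_per_h"]),
        cl_hepatic=float(sp["cl_hepatic_L_per_h"]),
        mw=cfg.get("mw_g_per_mol"),
        logd_74=cfg.get("logd_74"),
        pka_acidic=cfg.get("pka_acidic"),
        pka_basic=cfg.get("pka_basic"),
        solubility_ref=cfg.get("solubility_ref_mg_per_L"),
        diffusion_coeff=cfg.get("diffusion_coeff_cm_per_s2"),
    )


def load_compound(species: str, path=None) -> CompoundParams:
    """Shorthand: load the packaged (or given) config and resolve one species."""
    return compound_from_config(load_compound_config(path), species)
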
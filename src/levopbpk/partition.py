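"""Tissue partitioning: Kp / fut bookkeeping, unbound exposure ratios, Kp fitting.

A :class:`PartitionSet` maps each tissue to a total tissue:plasma partition
coefficient Kp and a fraction unbound in tissue fut. Unbound interstitial
concentrations are ``fut * C_tissue,total`` — the quantity a microdialysis
probe samples. The unbound tissue-to-plasma exposure ratio

    Kp,uu = AUC_free,tissue / AUC_free,plasma

equals ``fut * Kp / fu`` at the periodic steady state of a perfusion-limited
model with no elimination in the tissue; :func:`analytic_kpuu` is that closed
form and serves as the oracle for the simulated ratio.

Kp and fut are model inputs here (measured or literature values); the one
estimation task supported is :func:`fit_kp`, which recovers a single tissue's
Kp from observed unbound tissue concentrations — the route by which efflux at
the prostate is absorbed into a lower effective Kp instead of an explicit
transporter model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from ._round import round_half_up
from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateDataError,
    DomainError,
    ValidationError,
)


@dataclass(frozen=True)
class PartitionEntry:
    kp: float  # tissue:plasma total-concentration partition coefficient
    fut: float  # fraction unbound in tissue

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ValidationError("kp must be > 0")
        if not 0 < self.fut <= 1:
            raise ValidationError("fut must be in (0, 1]")


@dataclass(frozen=True)
class PartitionSet:
    species: str
    entries: Mapping[str, PartitionEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    def kp(self, tissue: str) -> float:
        return self.entries[tissue].kp

    def fut(self, tissue: str) -> float:
        return self.entries[tissue].fut

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.entries

    def with_kp(self, tissue: str, kp: float) -> "PartitionSet":
        """Copy with one tissue's Kp replaced (fut unchanged)."""
        new = dict(self.entries)
        new[tissue] = PartitionEntry(kp=kp, fut=new[tissue].fut)
        return PartitionSet(species=self.species, entries=new)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "entries": {
                k: {"kp": v.kp, "fut": v.fut} for k, v in self.entries.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionSet":
        return cls(
            species=d["species"],
            entries={
                k: PartitionEntry(kp=float(v["kp"]), fut=float(v["fut"]))
                for k, v in d["entries"].items()
            },
        )


def unbound_concentration(c_total_tissue, fut: float):
    """Unbound (ISF) concentration, ``fut * C_total`` [µg/mL]."""
    c = np.asarray(c_total_tissue, dtype=float)
    if np.any(c < 0):
        raise ValidationError("total tissue concentration must be >= 0")
    if not 0 < fut <= 1:
        raise ValidationError("fut must be in (0, 1]")
    out = fut * c
    return float(out) if np.isscalar(c_total_tissue) else out


def kpuu_from_aucs(auc_free_tissue: float, auc_free_plasma: float) -> float:
    """Kp,uu as the ratio of unbound AUCs, reported to 2 decimals."""
    if auc_free_plasma <= 0:
        raise DomainError("auc_free_plasma must be > 0")
    if auc_free_tissue <= 0:
        raise DomainError("auc_free_tissue must be > 0")
    return round_half_up(auc_free_tissue / auc_free_plasma, 2)


def analytic_kpuu(kp: float, fut: float, fu_plasma: float) -> float:
    """Closed-form steady-state Kp,uu = fut * Kp / fu for a passive tissue."""
    if min(kp, fut, fu_plasma) <= 0:
        raise DomainError("kp, fut and fu_plasma must all be > 0")
    return fut * kp / fu_plasma


def calibrated_partition_set(
    physiology,
    compound,
    known: Mapping[str, Mapping[str, float]],
    vss_target: float,
) -> PartitionSet:
    """Build a full PartitionSet from the measured entries plus a Vss match.

    Tissues with printed Kp/fut (``known``) keep those values; every other
    distributing tissue receives one shared Kp solved in closed form so that
    the model's steady-state volume of distribution

        Vss = V_blood + sum_t (Kp_t / Rbp) * V_t

    equals ``vss_target`` [L]. This is a declared calibration (the only
    constraint the published record puts on non-target tissues), not a
    prediction. Calibrated tissues get ``fut = fu / Kp`` — the purely passive
    convention under which their Kp,uu is exactly 1.
    """
    rbp = compound.rbp
    distributing = [physiology.lung] + list(physiology.parallel_tissues)
    v_known = 0.0
    v_unknown = 0.0
    known_term = 0.0
    for t in distributing:
        if t.name in known:
            known_term += float(known[t.name]["kp"]) / rbp * t.volume
            v_known += t.volume
        else:
            v_unknown += t.volume
    if v_unknown <= 0:
        raise ConfigurationError("no tissues left to calibrate")
    kp_rest = rbp * (vss_target - physiology.blood_volume - known_term) / v_unknown
    if kp_rest <= 0:
        raise ConfigurationError(
            f"Vss target {vss_target} L is not attainable: calibrated Kp "
            f"would be {kp_rest:.4g}"
        )
    entries: dict[str, PartitionEntry] = {}
    for t in distributing:
        if t.name in known:
            entries[t.name] = PartitionEntry(
                kp=float(known[t.name]["kp"]), fut=float(known[t.name]["fut"])
            )
        else:
            entries[t.name] = PartitionEntry(
                kp=kp_rest, fut=min(1.0, compound.fu_plasma / kp_rest)
            )
    return PartitionSet(species=physiology.species, entries=entries)


def fit_kp(
    observed,
    model,
    tissue: str,
    bounds: tuple[float, float] = (0.1, 50.0),
    residual: str = "log",
    regimen=None,
    xatol: float = 1e-4,
) -> dict:
    """Fit one tissue's Kp to observed unbound tissue concentrations.

    Minimizes the sum of squared residuals between simulated unbound
    concentrations (``fut * C_t``) and the uncensored observations for
    ``tissue``, over Kp in ``bounds`` by bounded scalar minimization
    (deterministic; no random seed involved).

    ``residual='log'`` (default) uses log residuals — proportional error,
    appropriate for concentration data spanning a decay and invariant under
    rescaling of all observations; ``'linear'`` uses additive residuals.

    ``observed`` is an :class:`~levopbpk.synthdata.ObservedDataset`; the dose
    regimen is taken from ``observed.meta['regimen']`` unless given.
    """
    from .engine import simulate  # local import: engine depends on this module

    if residual not in ("log", "linear"):
        raise ValidationError("residual must be 'log' or 'linear'")
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValidationError("bounds must be positive and increasing")
    frame = observed.frame
    mask = (
        (frame["compartment"] == tissue)
        & (frame["binding_state"] == "unbound")
        & (~frame["censored"])
    )
    obs = frame.loc[mask]
    if len(obs) < 3:
        raise DegenerateDataError(
            f"need >= 3 uncensored unbound observations for {tissue!r}, "
            f"got {len(obs)}"
        )
    t_obs = obs["time_h"].to_numpy(dtype=float)
    c_obs = obs["concentration_ug_per_mL"].to_numpy(dtype=float)
    if np.all(c_obs <= 0):
        raise DegenerateDataError("observed concentrations are identically zero")
    if residual == "log" and np.any(c_obs <= 0):
        raise DegenerateDataError("log residuals need strictly positive observations")
    if regimen is None:
        regimen = observed.meta.get("regimen")
    if regimen is None:
        raise ValidationError("no dose regimen supplied (argument or observed.meta)")

    order = np.argsort(t_obs)
    t_sorted = np.unique(t_obs[order])
    fut = model.partition.fut(tissue)
    trace: list[tuple[float, float]] = []

    def objective(kp: float) -> float:
        m = model.with_kp(tissue, kp)
        sim = simulate(m, regimen, t_end=float(t_sorted[-1]), t_eval=t_sorted)
        pred_at = dict(zip(sim.times, fut * sim.conc[tissue]))
        pred = np.array([pred_at[t] for t in t_obs])
        if residual == "log":
            pred = np.maximum(pred, 1e-12)
            r = np.log(pred) - np.log(c_obs)
        else:
            r = pred - c_obs
        val = float(np.sum(r * r))
        trace.append((kp, val))
        return val

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    if not res.success:
        raise ConvergenceError(
            f"Kp optimization failed in bounds {bounds}: {res.message}; "
            f"trace={trace[-5:]}"
        )
    kp_hat = float(res.x)
    if kp_hat - lo < 2 * xatol or hi - kp_hat < 2 * xatol:
        raise ConvergenceError(
            f"minimum pinned to bounds {bounds} at Kp={kp_hat:.4g} "
            f"(objective {res.fun:.4g}); widen the bounds; trace={trace[-5:]}"
        )
    return {
        "kp": kp_hat,
        "objective": float(res.fun),
        "n_obs": int(len(obs)),
        "residual": residual,
    }
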
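"""Model qualification: PRED/OBS ratios, the two-fold gate, population bands.

A PBPK model is deemed adequate when every simulated exposure metric lies
within two-fold of its observed counterpart (0.5 <= PRED/OBS <= 2.0, both
boundaries inclusive). Population variability is layered on the deterministic
model by log-normal perturbation of clearance, tissue Kp values and cardiac
output, with per-subject RNG substreams spawned from one root seed so a run
is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._round import round_half_up
from .engine import DoseEvent, Model, simulate
from .errors import DomainError, InputError, ValidationError
from .exposure import auc_trapezoid
from .partition import PartitionEntry, PartitionSet
from .physiology import apply_anesthesia

#: default log-normal coefficients of variation for virtual populations.
#: These are assumptions typical of PBPK population settings, not measured
#: values; every report records the CVs actually used.
DEFAULT_VARIABILITY = {"cl": 0.25, "kp": 0.20, "co": 0.15}


def pred_obs_ratio(simulated: float, observed: float) -> float:
    """Simulated/observed, reported to 2 decimals."""
    if observed <= 0:
        raise DomainError("observed must be > 0")
    if simulated < 0:
        raise DomainError("simulated must be >= 0")
    return round_half_up(simulated / observed, 2)


def twofold_gate(ratio: float) -> bool:
    """Acceptance gate: 0.5 <= ratio <= 2.0 (inclusive on both ends)."""
    if ratio <= 0:
        raise DomainError("ratio must be > 0")
    return 0.5 <= ratio <= 2.0


@dataclass(frozen=True)
class VerificationReport:
    """Rows of metric -> observed, simulated, 90% CI, ratio, two-fold flag."""

    frame: pd.DataFrame
    header: Mapping = None

    @property
    def all_pass(self) -> bool:
        return bool(self.frame["pass_twofold"].all())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def verification_report(
    observed: Mapping[str, float],
    simulated: Mapping[str, float],
    ci90: Optional[Mapping[str, tuple]] = None,
    header: Optional[Mapping] = None,
) -> VerificationReport:
    """Build a PRED/OBS report over matching metric names."""
    missing = set(observed) - set(simulated)
    if missing:
        raise InputError(f"simulated values missing for metrics {sorted(missing)}")
    rows = []
    for metric, obs in observed.items():
        sim = simulated[metric]
        ratio = pred_obs_ratio(sim, obs)
        lo, hi = (ci90 or {}).get(metric, (np.nan, np.nan))
        rows.append(
            {
                "metric": metric,
                "observed": obs,
                "simulated": sim,
                "ci90_low": lo,
                "ci90_high": hi,
                "ratio": ratio,
                "pass_twofold": twofold_gate(ratio),
            }
        )
    return VerificationReport(frame=pd.DataFrame(rows), header=dict(header or {}))


def ci_of_mean(values: Sequence[float], level: float = 0.90) -> tuple[float, float]:
    """Normal-approximation CI of the mean across subjects."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InputError("need >= 2 values for a CI")
    z = norm.ppf(0.5 + level / 2)
    half = z * v.std(ddof=1) / np.sqrt(len(v))
    m = v.mean()
    return float(m - half), float(m + half)


@dataclass(frozen=True)
class PopulationBands:
    """Pointwise percentile bands of a virtual-population simulation."""

    times: np.ndarray  # h
    bands: Mapping[str, dict]  # compartment -> {'p5','p50','p95'} arrays
    n_subjects: int
    seed: int
    variability: Mapping[str, float]
    subject_plasma_auc: np.ndarray  # per-subject plasma total AUC0-t_end

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, b in self.bands.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "compartment": comp,
                        "p5": b["p5"],
                        "p50": b["p50"],
                        "p95": b["p95"],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _perturb_model(model: Model, variability: Mapping[str, float], rng) -> Model:
    """One virtual subject: log-normal, median-preserving perturbations."""

    def factor(cv: float) -> float:
        if cv < 0:
            raise ValidationError("CVs must be >= 0")
        if cv == 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv * cv))
        return float(rng.lognormal(mean=0.0, sigma=sigma))

    compound = model.compound
    cv_cl = variability.get("cl", 0.0)
    if cv_cl > 0:
        compound = compound.scaled(factor(cv_cl))
    partition = model.partition
    cv_kp = variability.get("kp", 0.0)
    if cv_kp > 0:
        entries = {
            name: PartitionEntry(kp=e.kp * factor(cv_kp), fut=e.fut)
            for name, e in partition.entries.items()
        }
        partition = PartitionSet(species=partition.species, entries=entries)
    physiology = model.physiology
    cv_co = variability.get("co", 0.0)
    if cv_co > 0:
        co_per_kg = physiology.cardiac_output / physiology.body_weight
        physiology = apply_anesthesia(physiology, co_per_kg * factor(cv_co))
    return Model(physiology=physiology, compound=compound, partition=partition)


def population_simulate(
    model: Model,
    regimen: Sequence[DoseEvent],
    n: int,
    variability: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    t_end: float = 24.0,
    output_step: float = 0.1,
    compartments: Optional[Sequence[str]] = None,
) -> PopulationBands:
    """Simulate ``n`` virtual subjects and return 5/50/95 percentile bands.

    Perturbed parameters (per ``variability`` CV map, keys ``cl``, ``kp``,
    ``co``) are log-normal with median at the deterministic value. Each
    subject draws from its own substream spawned from ``seed``; identical
    seeds give bit-identical bands.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    variability = dict(DEFAULT_VARIABILITY if variability is None else variability)
    streams = np.random.SeedSequence(seed).spawn(n)
    track = list(compartments) if compartments else ["plasma", "lung", "prostate"]
    track = [
        c
        for c in track
        if c == "plasma" or model.physiology.has_tissue(c)
    ]
    profiles: dict[str, list[np.ndarray]] = {c: [] for c in track}
    aucs = []
    times = None
    for ss in streams:
        rng = np.random.default_rng(ss)
        subject = _perturb_model(model, variability, rng)
        sim = simulate(subject, regimen, t_end=t_end, output_step=output_step)
        times = sim.times
        for c in track:
            profiles[c].append(
                sim.plasma_total if c == "plasma" else sim.conc[c]
            )
        aucs.append(auc_trapezoid(sim.times, sim.plasma_total))
    bands = {}
    for c in track:
        mat = np.vstack(profiles[c])
        p5, p50, p95 = np.percentile(mat, [5, 50, 95], axis=0)
        bands[c] = {"p5": p5, "p50": p50, "p95": p95}
    return PopulationBands(
        times=times,
        bands=bands,
        n_subjects=n,
        seed=seed,
        variability=variability,
        subject_plasma_auc=np.array(aucs),
    )
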
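"""Synthetic observed datasets and packaged reference-table fixtures.

The source microdialysis/plasma datasets behind the model are not published
as concentration-time points, so tests and examples generate stand-ins: the
model's own truth profiles sampled on a sparse schedule, multiplied by
proportional log-normal noise, censored below a quantification limit. The
emulation targets the structure of the real data (sparse sampling, unbound
tissue + total plasma matrices, proportional error spanning ~2 decades), not
any particular measured values.

``load_fixture`` returns the packaged published summary tables (verification
AUCs, attainment grids, parameter records) as structured data.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import DoseEvent, Model, simulate
from .errors import InputError, ValidationError

DEFAULT_LLOQ = 0.01  # µg/mL

#: declared emulation choices for sampling schedules (not measured facts):
#: rat — every 20 min over 0-6 h post-bolus; human lung — every 30 min, 0-8 h
RAT_SCHEDULE = tuple(np.round(np.arange(1, 19) * (1 / 3), 6))
HUMAN_LUNG_SCHEDULE = tuple(np.round(np.arange(1, 17) * 0.5, 6))


@dataclass
class ObservedDataset:
    """Tidy observation records plus generation metadata.

    ``frame`` columns: time_h, concentration_ug_per_mL, compartment,
    binding_state ('total' | 'unbound'), subject, censored. Censored records
    (below LLOQ) carry NaN concentration and the flag; uncensored records are
    strictly positive.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def n_censored(self) -> int:
        return int(self.frame["censored"].sum())


def _default_binding(compartment: str) -> str:
    # plasma is assayed as total drug; microdialysis tissues as unbound
    return "total" if compartment == "plasma" else "unbound"


def generate_observations(
    model: Model,
    regimen: Sequence[DoseEvent],
    schedule: Sequence[float],
    compartments: Sequence,
    noise_cv: float = 0.15,
    lloq: float = DEFAULT_LLOQ,
    n_subjects: int = 1,
    seed: int = 0,
) -> ObservedDataset:
    """Sample noisy observations from a model's truth profiles.

    ``compartments`` entries are names ('plasma', 'lung', 'prostate', ...) or
    (name, binding_state) pairs; the default binding is total for plasma and
    unbound for tissues. Noise is multiplicative log-normal with the given
    CV and median 1, i.i.d. across records; values below ``lloq`` are
    censored (NaN + flag). Deterministic under ``seed``.
    """
    schedule = np.asarray(sorted(schedule), dtype=float)
    if len(schedule) == 0:
        raise InputError("empty sampling schedule")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    comps = []
    for c in compartments:
        if isinstance(c, str):
            comps.append((c, _default_binding(c)))
        else:
            name, state = c
            if state not in ("total", "unbound"):
                raise ValidationError(f"unknown binding state {state!r}")
            comps.append((name, state))

    sim = simulate(model, regimen, t_end=float(schedule[-1]), t_eval=schedule)
    truth = {}
    for name, state in comps:
        if name == "plasma":
            prof = sim.plasma_total if state == "total" else sim.plasma_unbound
        else:
            prof = sim.conc[name] if state == "total" else sim.unbound(name)
        truth[(name, state)] = np.interp(schedule, sim.times, prof)

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv * noise_cv)) if noise_cv > 0 else 0.0
    rows = []
    for subject in range(1, n_subjects + 1):
        for (name, state), prof in truth.items():
            noise = (
                rng.lognormal(mean=0.0, sigma=sigma, size=len(schedule))
                if sigma > 0
                else np.ones(len(schedule))
            )
            values = prof * noise
            censored = values < lloq
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": schedule,
                        "concentration_ug_per_mL": np.where(
                            censored, np.nan, values
                        ),
                        "compartment": name,
                        "binding_state": state,
                        "subject": subject,
                        "censored": censored,
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True)
    meta = {
        "species": model.physiology.species,
        "regimen": list(regimen) if not isinstance(regimen, DoseEvent) else [regimen],
        "noise_model": "proportional lognormal",
        "noise_cv": noise_cv,
        "lloq": lloq,
        "seed": seed,
        "truth_params": {
            name: {"kp": model.partition.kp(name), "fut": model.partition.fut(name)}
            for name, _ in comps
            if name in model.partition
        },
        "synthetic": True,
    }
    return ObservedDataset(frame=frame, meta=meta)


def load_fixture(name: str):
    """Load a packaged reference table by manifest name.

    CSV fixtures return a DataFrame; JSON fixtures return a dict. The dict
    form carries a ``source`` citation field from the manifest.
    """
    pkg = importlib.resources.files("levopbpk.data") / "fixtures"
    manifest = json.loads((pkg / "manifest.json").read_text())
    try:
        entry = manifest["fixtures"][name]
    except KeyError:
        raise InputError(
            f"unknown fixture {name!r}; available: "
            f"{sorted(manifest['fixtures'])}"
        ) from None
    path = pkg / entry["file"]
    if entry["file"].endswith(".csv"):
        with importlib.resources.as_file(path) as p:
            return pd.read_csv(p)
    data = json.loads(path.read_text())
    if isinstance(data, dict):
        data.setdefault("source", manifest["source"])
        data.setdefault("description", entry["description"])
    return data
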
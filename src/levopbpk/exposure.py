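"""Non-compartmental exposure metrics on simulated or observed profiles.

Linear trapezoidal AUC, log-linear terminal slope (λz), extrapolation to
infinity, and the model's steady-state volume of distribution. The linear
(not linear-up/log-down) trapezoid is used throughout: profiles here are
dense simulated grids on which the variants agree to well below 0.1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import linregress

from .errors import DomainError, InputError


@dataclass(frozen=True)
class ExposureSummary:
    auc_0_t: float  # µg·h/mL
    auc_0_inf: float  # µg·h/mL
    lambda_z: float  # 1/h
    extrapolated_fraction: float
    cmax: float  # µg/mL
    tmax: float  # h
    r2: float  # terminal-fit quality


def _check_profile(times, concs):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or c.shape != t.shape or len(t) < 2:
        raise InputError("times and concs must be equal-length 1-D with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    if np.any(c < 0):
        raise InputError("concentrations must be >= 0")
    return t, c


def auc_trapezoid(times, concs) -> float:
    """Linear trapezoidal AUC [µg·h/mL]."""
    t, c = _check_profile(times, concs)
    return float(np.trapezoid(c, t))


def terminal_slope(times, concs, n_points: int = 5) -> dict:
    """Log-linear regression on the last ``n_points``: {'lambda_z', 'r2'}.

    λz is minus the slope of ln(C) vs t. A profile that is not declining
    yields λz <= 0, which :func:`extrapolate_auc` rejects downstream. A
    quality warning is emitted when the fit is poor (r² < 0.99) or the fitted
    stretch spans less than two estimated half-lives.
    """
    t, c = _check_profile(times, concs)
    if n_points < 3:
        raise InputError("n_points must be >= 3")
    if n_points > len(t):
        raise InputError(f"profile has only {len(t)} points, need {n_points}")
    tt, cc = t[-n_points:], c[-n_points:]
    if np.any(cc <= 0):
        raise DomainError("terminal concentrations must be > 0 for a log-linear fit")
    fit = linregress(tt, np.log(cc))
    lambda_z = -float(fit.slope)
    r2 = float(fit.rvalue**2)
    if lambda_z > 0:
        span_halflives = (tt[-1] - tt[0]) * lambda_z / np.log(2)
        if r2 < 0.99 or span_halflives < 2.0:
            warnings.warn(
                f"terminal fit quality low (r2={r2:.4f}, "
                f"{span_halflives:.2f} half-lives spanned); AUC extrapolation "
                "may be unreliable",
                stacklevel=2,
            )
    return {"lambda_z": lambda_z, "r2": r2}


def extrapolate_auc(auc_0_t: float, c_last: float, lambda_z: float) -> float:
    """AUC0-inf = AUC0-t + C_last / λz."""
    if lambda_z <= 0:
        raise DomainError("lambda_z must be > 0 for extrapolation")
    if c_last < 0 or auc_0_t < 0:
        raise InputError("auc_0_t and c_last must be >= 0")
    return auc_0_t + c_last / lambda_z


def nca(times, concs, n_terminal: int = 5) -> ExposureSummary:
    """Full non-compartmental summary of one profile."""
    t, c = _check_profile(times, concs)
    auc_t = auc_trapezoid(t, c)
    fit = terminal_slope(t, c, n_points=n_terminal)
    auc_inf = extrapolate_auc(auc_t, float(c[-1]), fit["lambda_z"])
    i = int(np.argmax(c))
    return ExposureSummary(
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=fit["lambda_z"],
        extrapolated_fraction=1.0 - auc_t / auc_inf,
        cmax=float(c[i]),
        tmax=float(t[i]),
        r2=fit["r2"],
    )


def model_vss(model) -> float:
    """Steady-state volume of distribution [L], blood-referenced:
    V_blood + Σ (Kp_t / Rbp) · V_t over the lung and all parallel tissues."""
    phys = model.physiology
    vss = phys.blood_volume
    for t in [phys.lung] + list(phys.parallel_tissues):
        vss += model.kp_blood(t.name) * t.volume
    return float(vss)
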
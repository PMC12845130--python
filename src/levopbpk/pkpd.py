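"""fAUC/MIC target attainment for fluoroquinolone dosing.

The efficacy index is the steady-state free AUC over one dosing interval
divided by the pathogen's highest susceptible MIC (CLSI breakpoint). For
fluoroquinolones an fAUC/MIC of at least 30 is the accepted target; the
threshold is applied inclusively (≥ 30). Ratios are reported to one decimal,
rounded half-up, which reproduces the published tables cell for cell.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._round import round_half_up
from .errors import DomainError, InputError, ValidationError

ATTAINMENT_TARGET = 30.0


@dataclass(frozen=True)
class BreakpointTable:
    """Pathogen -> highest susceptible MIC [mg/L], with a source label."""

    mics: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mics", dict(self.mics))
        if not self.mics:
            raise ValidationError("breakpoint table is empty")
        for p, m in self.mics.items():
            if m <= 0:
                raise ValidationError(f"MIC for {p!r} must be > 0")

    def mic(self, pathogen: str) -> float:
        try:
            return self.mics[pathogen]
        except KeyError:
            raise InputError(f"no breakpoint for pathogen {pathogen!r}") from None

    @property
    def pathogens(self) -> tuple[str, ...]:
        return tuple(self.mics)

    @classmethod
    def from_csv(cls, path=None) -> "BreakpointTable":
        """Load breakpoints from CSV (default: the packaged CLSI table)."""
        if path is None:
            pkg = importlib.resources.files("levopbpk.data")
            path = pkg / "breakpoints_clsi.csv"
        df = pd.read_csv(path)
        source = df["source"].iloc[0] if "source" in df else ""
        return cls(
            mics=dict(zip(df["pathogen"], df["susceptible_mic_mg_L"])),
            source=str(source),
        )


def fauc_mic(auc_free_tau: float, mic: float) -> float:
    """fAUC/MIC index (reported to 1 decimal). µg·h/mL ≡ mg·h/L, so the
    quotient is the customary index carrying hours."""
    if mic <= 0:
        raise DomainError("mic must be > 0")
    if auc_free_tau < 0:
        raise DomainError("auc_free_tau must be >= 0")
    return round_half_up(auc_free_tau / mic, 1)


def classify_attainment(ratio: float, target: float = ATTAINMENT_TARGET) -> bool:
    """True when the target is attained (inclusive: ratio >= target)."""
    if ratio < 0:
        raise DomainError("ratio must be >= 0")
    return ratio >= target


@dataclass
class AttainmentTable:
    """Pathogen × regimen fAUC/MIC table (the machine twin of the published
    attainment tables). ``frame`` holds the rounded ratios (NaN where a cell
    is flagged not-calculated)."""

    frame: pd.DataFrame  # ratios; index=pathogen, columns=regimen
    attained: pd.DataFrame  # booleans (False where NC)
    nc: pd.DataFrame  # not-calculated flags
    auc_free_tau: Mapping  # regimen -> µg·h/mL
    target: float = ATTAINMENT_TARGET

    def cell(self, pathogen: str, regimen) -> dict:
        return {
            "ratio": None
            if bool(self.nc.loc[pathogen, regimen])
            else float(self.frame.loc[pathogen, regimen]),
            "attained": bool(self.attained.loc[pathogen, regimen]),
            "nc_flag": bool(self.nc.loc[pathogen, regimen]),
        }

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "pathogen"
        out.to_csv(path)

    def report(self) -> str:
        """Flag-annotated text table: ratio plus [+] attained / [-] missed /
        NC not calculated."""
        lines = [
            f"fAUC/MIC target attainment (target >= {self.target:g})",
            f"steady-state free AUC per interval: "
            + ", ".join(f"{k}: {v:g}" for k, v in self.auc_free_tau.items()),
        ]
        header = ["pathogen".ljust(22)] + [str(c).rjust(12) for c in self.frame.columns]
        lines.append("".join(header))
        for p in self.frame.index:
            row = [str(p).ljust(22)]
            for c in self.frame.columns:
                if self.nc.loc[p, c]:
                    row.append("NC".rjust(12))
                else:
                    mark = "+" if self.attained.loc[p, c] else "-"
                    row.append(f"{self.frame.loc[p, c]:.1f} [{mark}]".rjust(12))
            lines.append("".join(row))
        return "\n".join(lines)


def build_attainment_table(
    aucs: Mapping,
    breakpoints: BreakpointTable,
    nc_rules: Optional[Iterable[tuple]] = None,
    target: float = ATTAINMENT_TARGET,
) -> AttainmentTable:
    """Cross every pathogen with every regimen's free interval AUC.

    ``aucs`` maps regimen label (e.g. dose in mg) -> steady-state free AUC
    over the dosing interval [µg·h/mL]. ``nc_rules`` is a set of
    (pathogen, regimen) cells to flag as not-calculated, mirroring published
    table conventions; flagged cells carry no ratio.
    """
    if not aucs:
        raise InputError("no regimens supplied")
    nc_set = {(p, r) for p, r in (nc_rules or ())}
    pathogens = list(breakpoints.pathogens)
    regimens = list(aucs)
    ratio = pd.DataFrame(index=pathogens, columns=regimens, dtype=float)
    attained = pd.DataFrame(False, index=pathogens, columns=regimens)
    nc = pd.DataFrame(False, index=pathogens, columns=regimens)
    for p in pathogens:
        mic = breakpoints.mic(p)
        for r in regimens:
            if (p, r) in nc_set:
                nc.loc[p, r] = True
                continue
            val = fauc_mic(float(aucs[r]), mic)
            ratio.loc[p, r] = val
            attained.loc[p, r] = classify_attainment(val, target)
    return AttainmentTable(
        frame=ratio, attained=attained, nc=nc, auc_free_tau=dict(aucs), target=target
    )
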
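"""Dose -> average CSF concentration, with the unit conversions used downstream.

The steady-state average concentration for a once-daily oral dose is

    C_ave = F * D / (CL * tau) * Kp / M * 1e6   [nM]

where F is bioavailability (fraction), D the daily dose (mg), CL the
volume-normalized clearance (L/hr), tau the dose interval (hr), Kp the
brain/blood transfer ratio (applied to the plasma concentration to obtain the
brain/CSF level), and M the molecular weight (g/mol) converting mg/L to nM.
Linear (dose-proportional) pharmacokinetics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .errors import UnknownDrug


@dataclass(frozen=True)
class DrugPK:
    """Per-drug pharmacokinetic constants.

    ``CL`` is volume-normalized clearance in L/hr (the standard reading that
    makes F*D/(CL*tau) a plasma concentration in mg/L).
    """

    name: str
    F: float  # bioavailability, fraction in (0, 1]
    CL: float  # clearance, L/hr
    tau: float  # dose interval, hr
    Kp: float  # brain(CSF)/blood transfer ratio
    M: float  # molecular weight, g/mol

    def __post_init__(self) -> None:
        if not 0 < self.F <= 1:
            raise ValueError(f"{self.name}: F must be in (0, 1], got {self.F}")
        for attr in ("CL", "tau", "Kp", "M"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")


@dataclass(frozen=True)
class Regimen:
    """One subject's medication map (drug name -> daily dose, mg) at one epoch."""

    doses: Dict[str, float] = field(default_factory=dict)
    epoch: str = "post"  # 'pre' | 'post'

    def __post_init__(self) -> None:
        for drug, dose in self.doses.items():
            if dose < 0:
                raise ValueError(f"negative dose for {drug}: {dose}")

    def items(self):
        return self.doses.items()

    def __len__(self) -> int:
        return len(self.doses)


def average_csf_concentration(dose_mg: float, pk: DrugPK) -> float:
    """Average CSF concentration in nM for a daily oral dose in mg/day."""
    if pk is None:
        raise UnknownDrug("missing pharmacokinetic record")
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    c_plasma_mg_per_L = pk.F * dose_mg / (pk.CL * pk.tau)
    c_brain_mg_per_L = c_plasma_mg_per_L * pk.Kp
    return c_brain_mg_per_L / pk.M * 1e6  # mg/L -> nM


def nM_to_ng_per_g(c_nM: float, M: float) -> float:
    """nM -> ng per gram of tissue, assuming tissue density 1 g/mL.

    1 nmol/L of a compound with molecular weight M g/mol is M ng/L,
    i.e. M/1000 ng/mL = M/1000 ng/g.
    """
    if c_nM < 0:
        raise ValueError("concentration must be >= 0")
    return c_nM * M / 1000.0


def ng_per_g_to_nM(c_ng_per_g: float, M: float) -> float:
    """Inverse of :func:`nM_to_ng_per_g`."""
    return c_ng_per_g * 1000.0 / M


def nM_to_uM(c_nM: float) -> float:
    return c_nM / 1000.0
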
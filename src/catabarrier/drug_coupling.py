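"""Drug CSF concentrations -> multiplicative transforms of the model parameters.

Each mechanism produces a :class:`ParameterTransform` (a map parameter ->
multiplicative factor); multi-drug effects compose by elementwise product
(commutative).  The composed raw transform is then blended with the baseline
through the medication response factor ``a``::

    p' = p0 + a * (p_raw - p0)

so that ``a`` scales the *change* in each parameter and the system retains
its bistable structure over the clinical dose range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .errors import DomainError, RegimeError, UnknownReceptor
from .model_core import PARAM_NAMES, ModelParams, bistable_triple
from .pharmacokinetics import average_csf_concentration, nM_to_ng_per_g, nM_to_uM
from .registry import (
    RECEPTORS,
    BenzoConstants,
    DrugRegistry,
    DrugSpec,
    EndogenousReceptorTone,
    LamotrigineConstants,
)

#: multiplicative factors are floored here to avoid sign flips at extreme doses
FACTOR_FLOOR = 0.05


@dataclass(frozen=True)
class CouplingConfig:
    """Population-wide response factor and regime guard."""

    response_factor: float = 0.35
    regime_guard: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.response_factor <= 1:
            raise ValueError("response_factor must be in [0, 1]")


@dataclass
class ParameterTransform:
    """Map parameter name -> multiplicative factor, with provenance.

    Untouched parameters have factor exactly 1.  Composition is the
    elementwise product, hence order-independent.
    """

    factors: Dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in PARAM_NAMES}
    )
    provenance: List[Tuple[str, str, str, float]] = field(default_factory=list)
    # provenance entries: (drug, mechanism, parameter, factor)

    @classmethod
    def identity(cls) -> "ParameterTransform":
        return cls()

    @classmethod
    def from_factors(
        cls, factors: Dict[str, float], drug: str = "", mechanism: str = ""
    ) -> "ParameterTransform":
        full = {k: 1.0 for k in PARAM_NAMES}
        prov = []
        for k, v in factors.items():
            if k not in PARAM_NAMES:
                raise KeyError(f"unknown model parameter {k!r}")
            full[k] = float(v)
            prov.append((drug, mechanism, k, float(v)))
        return cls(factors=full, provenance=prov)

    def compose(self, other: "ParameterTransform") -> "ParameterTransform":
        factors = {k: self.factors[k] * other.factors[k] for k in PARAM_NAMES}
        return ParameterTransform(
            factors=factors, provenance=self.provenance + other.provenance
        )

    def is_identity(self, tol: float = 0.0) -> bool:
        return all(abs(v - 1.0) <= tol for v in self.factors.values())

    def apply_raw(self, p: ModelParams) -> ModelParams:
        """Apply all factors without response-factor blending."""
        new = {}
        for k in PARAM_NAMES:
            f = self.factors[k]
            if f < FACTOR_FLOOR:
                warnings.warn(
                    f"factor {f:.3g} for {k} floored at {FACTOR_FLOOR}",
                    stacklevel=2,
                )
                f = FACTOR_FLOOR
            new[k] = getattr(p, k) * f
        return ModelParams(**new)


# ---------------------------------------------------------------------------
# lamotrigine (anticonvulsant)
# ---------------------------------------------------------------------------

def lamotrigine_transform(
    c_ltg_uM: float, consts: LamotrigineConstants | None = None, drug: str = "lamotrigine"
) -> ParameterTransform:
    """Compose the three lamotrigine mechanisms at CSF concentration ``c`` (uM).

    (i) Na+ block: dI_Na = 1 - (C/(C+K_C))^n; the excitability effect
    E_Na = 1 - p_lam*(1 - dI_Na) raises theta1 by 1/E_Na.
    (ii) Ih shift: dx1 = max(0, 1 - ih_slope*C); E_h analogous, raises theta1.
    (iii) glutamate release: dG = max(0, 1 - glu_slope*C); E_glu scales down
    w11 and w10.
    """
    if c_ltg_uM < 0:
        raise ValueError("concentration must be >= 0")
    c = float(c_ltg_uM)
    k = consts or LamotrigineConstants()

    d_na = 1.0 - (c / (c + k.K_C_uM)) ** k.n if c > 0 else 1.0
    e_na = 1.0 - k.p_lam * (1.0 - d_na)
    t_na = ParameterTransform.from_factors({"theta1": 1.0 / e_na}, drug, "Na_block")

    d_ih = max(0.0, 1.0 - k.ih_slope * c)
    e_ih = 1.0 - k.p_lam * (1.0 - d_ih)
    t_ih = ParameterTransform.from_factors({"theta1": 1.0 / e_ih}, drug, "Ih_shift")

    d_glu = max(0.0, 1.0 - k.glu_slope * c)
    e_glu = 1.0 - k.p_lam * (1.0 - d_glu)
    t_glu = ParameterTransform.from_factors(
        {"w11": e_glu, "w10": e_glu}, drug, "glutamate_release"
    )
    return t_na.compose(t_ih).compose(t_glu)


# ---------------------------------------------------------------------------
# benzodiazepines
# ---------------------------------------------------------------------------

def benzodiazepine_occupancy(
    c_ng_per_g: float, consts: BenzoConstants | None = None
) -> float:
    """GABA-A site occupancy R = C^A / (C^A + B_half), C in ng/g tissue."""
    if c_ng_per_g < 0:
        raise ValueError("concentration must be >= 0")
    k = consts or BenzoConstants()
    if c_ng_per_g == 0:
        return 0.0
    ca = c_ng_per_g ** k.A
    return ca / (ca + k.B_half)


def benzodiazepine_transform(R: float, drug: str = "benzodiazepine") -> ParameterTransform:
    """Scale the inhibitory synaptic weights w00, w01 by (1 + R)."""
    if not 0 <= R < 1:
        raise ValueError("occupancy must be in [0, 1)")
    return ParameterTransform.from_factors(
        {"w00": 1.0 + R, "w01": 1.0 + R}, drug, "GABA_A_potentiation"
    )


# ---------------------------------------------------------------------------
# antipsychotics: exact competitive binding + per-receptor effects
# ---------------------------------------------------------------------------

def competitive_occupancy(
    K_A: float, C_A: float, K_B: float, C_B: float, R_tot: float = 1.0
) -> float:
    """Endogenous-ligand receptor occupancy under exact two-ligand competition.

    Closed-form real root of the cubic equilibrium (mutually exclusive
    binding of ligands A and B to a receptor of total concentration
    ``R_tot``; all concentrations and affinities in the same unit, nM here):

        a = K_A + K_B + C_A + C_B - R_tot
        b = K_B*(C_A - R_tot) + K_A*(C_B - R_tot) + K_A*K_B
        c = -K_A*K_B*R_tot
        delta = arccos((-2a^3 + 9ab - 27c) / (2*sqrt((a^2-3b)^3)))
        R_oc  = C_A*(2*sqrt(a^2-3b)*cos(delta/3) - a)
                / (3*K_A + 2*sqrt(a^2-3b)*cos(delta/3) - a) / R_tot

    Returns the fraction of receptors occupied by the endogenous ligand A.
    """
    if K_A <= 0 or K_B <= 0:
        raise ValueError("affinities must be > 0")
    if C_A < 0 or C_B < 0:
        raise ValueError("concentrations must be >= 0")
    if R_tot <= 0:
        raise ValueError("R_tot must be > 0")
    a = K_A + K_B + C_A + C_B - R_tot
    b = K_B * (C_A - R_tot) + K_A * (C_B - R_tot) + K_A * K_B
    c = -K_A * K_B * R_tot
    disc = a * a - 3.0 * b
    if disc <= 0:
        raise DomainError("cubic discriminant non-positive")
    arg = (-2.0 * a**3 + 9.0 * a * b - 27.0 * c) / (2.0 * math.sqrt(disc**3))
    if arg > 1.0 + 1e-9 or arg < -1.0 - 1e-9:
        raise DomainError(f"arccos argument {arg} outside [-1, 1]")
    arg = min(1.0, max(-1.0, arg))
    delta = math.acos(arg)
    u = 2.0 * math.sqrt(disc) * math.cos(delta / 3.0) - a
    bound_A = C_A * u / (3.0 * K_A + u)
    return bound_A / R_tot


def competitive_occupancy_bisect(
    K_A: float, C_A: float, K_B: float, C_B: float, R_tot: float = 1.0,
    tol: float = 1e-12,
) -> float:
    """Independent equilibrium solver (bisection on free receptor).

    Solves the coupled mass-action/conservation system for the free receptor
    concentration and returns the endogenous-ligand occupancy.  Used as the
    numerical oracle for :func:`competitive_occupancy`.
    """
    def excess(r_free: float) -> float:
        a_free = C_A / (1.0 + r_free / K_A)
        b_free = C_B / (1.0 + r_free / K_B)
        return r_free * (1.0 + a_free / K_A + b_free / K_B) - R_tot

    lo, hi = 0.0, R_tot
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    r_free = 0.5 * (lo + hi)
    a_free = C_A / (1.0 + r_free / K_A)
    return (r_free * a_free / K_A) / R_tot


#: per-receptor coupling of the activation deviation dr = (R_oc-R_con)/R_con.
#: entries: parameter -> sign of dr in the factor (factor = 1 + sign*dr).
_RECEPTOR_COUPLING = {
    "D1": {"mu1": -1, "theta0": -1, "w11": +1, "w10": +1, "w01": +1},
    "D2": {"w11": -1, "w10": -1, "mu1": +1},
    "5HT1A": {"theta1": +1},
    "5HT2A": {"theta1": -1},
    "M1": {"theta1": -1},
}


def receptor_effect(
    receptor: str, R_oc: float, R_con: float, drug: str = ""
) -> ParameterTransform:
    """Parameter transform for one receptor's activation deviation.

    ``R_con`` is the control (drug-free) endogenous occupancy; antagonism
    gives R_oc < R_con, flipping the sign of each activation effect.
    """
    if receptor not in RECEPTORS:
        raise UnknownReceptor(f"unsupported receptor {receptor!r}")
    if not 0 < R_con < 1:
        raise ValueError("R_con must be in (0, 1)")
    dr = (R_oc - R_con) / R_con
    factors = {}
    for param, sign in _RECEPTOR_COUPLING[receptor].items():
        f = 1.0 + sign * dr
        if f <= 0:
            raise ValueError(
                f"{receptor} effect drives {param} factor to {f:.3g} <= 0"
            )
        factors[param] = f
    return ParameterTransform.from_factors(factors, drug, receptor)


def control_occupancy(tone: EndogenousReceptorTone, R_tot: float = 1.0) -> float:
    """Drug-free endogenous occupancy (C_B = 0) for a receptor's tone."""
    return competitive_occupancy(tone.K_A, tone.C_A, K_B=1.0, C_B=0.0, R_tot=R_tot)


def antipsychotic_transform(
    drug: DrugSpec,
    c_drug_nM: float,
    endogenous: Dict[str, EndogenousReceptorTone],
) -> ParameterTransform:
    """Compose receptor effects over the drug's affinity profile."""
    if c_drug_nM < 0:
        raise ValueError("concentration must be >= 0")
    t = ParameterTransform.identity()
    for receptor, K_B in (drug.receptors or {}).items():
        if receptor not in RECEPTORS:
            raise UnknownReceptor(f"unsupported receptor {receptor!r}")
        tone = endogenous[receptor]
        r_con = control_occupancy(tone)
        r_oc = competitive_occupancy(tone.K_A, tone.C_A, K_B, c_drug_nM)
        t = t.compose(receptor_effect(receptor, r_oc, r_con, drug=drug.name))
    return t


# ---------------------------------------------------------------------------
# full regimen
# ---------------------------------------------------------------------------

def regimen_transform(regimen, registry: DrugRegistry) -> ParameterTransform:
    """Composed raw transform of every drug in a regimen."""
    t = ParameterTransform.identity()
    for name, dose in regimen.items():
        spec = registry.get(name)
        if dose == 0 or spec.drug_class == "uncoupled":
            continue
        c_nM = average_csf_concentration(dose, spec.pk)
        if spec.drug_class == "anticonvulsant":
            t = t.compose(lamotrigine_transform(nM_to_uM(c_nM), spec.lamotrigine, name))
        elif spec.drug_class == "benzodiazepine":
            c_ng = nM_to_ng_per_g(c_nM, spec.pk.M)
            R = benzodiazepine_occupancy(c_ng, spec.benzo)
            t = t.compose(benzodiazepine_transform(R, name))
        elif spec.drug_class == "antipsychotic":
            t = t.compose(antipsychotic_transform(spec, c_nM, registry.endogenous))
    return t


def apply_regimen(
    p0: ModelParams,
    regimen,
    registry: DrugRegistry,
    cfg: CouplingConfig | None = None,
) -> ModelParams:
    """Transformed parameters p' = p0 + a*(p_raw - p0) for one regimen.

    With the regime guard on (default) a RegimeError is raised if the
    transformed parameters lose the three-fixed-point structure.
    """
    cfg = cfg or CouplingConfig()
    registry.validate_regimen_names(n for n, _ in regimen.items())
    t = regimen_transform(regimen, registry)
    p_raw = t.apply_raw(p0)
    a = cfg.response_factor
    blended = {
        k: getattr(p0, k) + a * (getattr(p_raw, k) - getattr(p0, k))
        for k in PARAM_NAMES
    }
    p_new = ModelParams(**blended)
    if cfg.regime_guard:
        try:
            bistable_triple(p_new)
        except RegimeError as exc:
            raise RegimeError(
                f"regimen {dict(regimen.items())!r} destroys bistability: {exc}"
            ) from exc
    return p_new


def provenance_log(regimen, registry: DrugRegistry) -> list:
    """JSON-able audit log drug -> mechanism -> parameter -> factor."""
    t = regimen_transform(regimen, registry)
    return [
        {"drug": d, "mechanism": m, "parameter": p, "factor": f}
        for d, m, p, f in t.provenance
    ]
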
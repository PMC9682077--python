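"""Drug registry: PK constants, mechanism class, and coupling constants.

The registry is the single auditable source for every per-drug number the
pipeline consumes.  All values ship as documented defaults (see
``docs/methods.md`` for provenance and rationale) and can be overridden from
a YAML/JSON file with the same structure.

Three mechanism classes are modeled:

* ``anticonvulsant`` (lamotrigine): Na+ -current block (saturating binding
  law), Ih shift and glutamate-release reduction (linear laws), coupled to
  theta1 / w11 / w10.
* ``benzodiazepine``: GABA-A potentiation via a Hill-type receptor-occupancy
  law, coupled to the inhibitory weights w00 / w01.
* ``antipsychotic``: competitive antagonism of endogenous transmitters at
  D1 / D2 / 5-HT1A / 5-HT2A / M1, coupled per receptor.

Drugs of class ``uncoupled`` exist so that realistic pre-treatment
polypharmacy can be represented; they carry placeholder PK records and have
no effect on model parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .errors import ConfigError, UnknownDrug
from .pharmacokinetics import DrugPK

RECEPTORS = ("D1", "D2", "5HT1A", "5HT2A", "M1")
DRUG_CLASSES = ("anticonvulsant", "benzodiazepine", "antipsychotic", "uncoupled")


@dataclass(frozen=True)
class LamotrigineConstants:
    """Coupling constants for the three lamotrigine mechanisms.

    ``K_C`` (uM) and Hill exponent ``n`` parameterize the Na+-channel block;
    ``ih_slope`` and ``glu_slope`` (per uM) are the linear laws for the Ih
    shift and glutamate-release reduction; ``p_lam`` is the shared fractional
    weight of each effect.
    """

    K_C_uM: float = 513.0
    n: float = 0.9
    p_lam: float = 0.15
    ih_slope: float = 0.004
    glu_slope: float = 0.004

    def __post_init__(self) -> None:
        if not (0 < self.p_lam < 1):
            raise ValueError("p_lam must be in (0, 1)")
        for a in ("K_C_uM", "n", "ih_slope", "glu_slope"):
            if getattr(self, a) <= 0:
                raise ValueError(f"{a} must be > 0")


@dataclass(frozen=True)
class BenzoConstants:
    """Hill-type occupancy law R = C^A / (C^A + B_half), C in ng/g."""

    A: float = 1.4328
    B_half: float = 73.89

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B_half <= 0:
            raise ValueError("A and B_half must be > 0")


@dataclass(frozen=True)
class EndogenousReceptorTone:
    """Endogenous transmitter affinity and tone at one receptor (both nM)."""

    K_A: float
    C_A: float

    def __post_init__(self) -> None:
        if self.K_A <= 0 or self.C_A <= 0:
            raise ValueError("K_A and C_A must be > 0")


@dataclass(frozen=True)
class DrugSpec:
    """One medication: PK record, mechanism class, and coupling constants."""

    name: str
    drug_class: str
    pk: DrugPK
    receptors: Optional[Dict[str, float]] = None  # receptor -> K_B (nM)
    benzo: Optional[BenzoConstants] = None
    lamotrigine: Optional[LamotrigineConstants] = None
    clinical_range: Tuple[float, float] = (0.0, 0.0)  # mg/day
    dose_step: float = 1.0  # formulary increment, mg

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise ConfigError(f"{self.name}: unknown class {self.drug_class!r}")
        if self.drug_class == "antipsychotic" and not self.receptors:
            raise ConfigError(f"{self.name}: antipsychotic needs a receptor profile")
        if self.drug_class == "benzodiazepine" and self.benzo is None:
            raise ConfigError(f"{self.name}: benzodiazepine needs occupancy constants")
        if self.receptors:
            for r, k in self.receptors.items():
                if r not in RECEPTORS:
                    raise ConfigError(f"{self.name}: unsupported receptor {r!r}")
                if k <= 0:
                    raise ConfigError(f"{self.name}: affinity at {r} must be > 0")


@dataclass
class DrugRegistry:
    drugs: Dict[str, DrugSpec]
    endogenous: Dict[str, EndogenousReceptorTone]

    def get(self, name: str) -> DrugSpec:
        try:
            return self.drugs[name]
        except KeyError:
            raise UnknownDrug(f"drug {name!r} not in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self.drugs

    def validate_regimen_names(self, names) -> None:
        missing = [n for n in names if n not in self.drugs]
        if missing:
            raise UnknownDrug(f"drugs missing from registry: {missing}")

    def coupled_drugs(self) -> list:
        return [d for d in self.drugs.values() if d.drug_class != "uncoupled"]


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

#: Endogenous transmitter tone per receptor (nM).  Dopamine burst tone feeds
#: D1 (phasic action) and tonic tone feeds D2 (sustained action); serotonin
#: and acetylcholine tone are shared by their receptors.
_DEFAULT_ENDOGENOUS = {
    "D1": EndogenousReceptorTone(K_A=1000.0, C_A=200.0),  # dopamine, burst
    "D2": EndogenousReceptorTone(K_A=25.0, C_A=37.0),  # dopamine, tonic
    "5HT1A": EndogenousReceptorTone(K_A=4.0, C_A=3.9),  # serotonin
    "5HT2A": EndogenousReceptorTone(K_A=200.0, C_A=3.9),  # serotonin
    "M1": EndogenousReceptorTone(K_A=300.0, C_A=10.0),  # acetylcholine
}

# Antipsychotic K_B values below are *effective* potency constants for the
# receptor-level modulation, not raw binding Ki: they preserve the relative
# potency ordering of the two drugs (clozapine strongly antimuscarinic /
# anti-5HT2A; olanzapine relatively D2-weighted) while keeping clinical CSF
# concentrations in the shallow, near-linear part of the competition curve.
_DEFAULT_DRUGS = [
    DrugSpec(
        name="clozapine",
        drug_class="antipsychotic",
        # F ~ 0.55 oral; CL ~ 30 L/hr; Kp = free CSF fraction (~97% protein bound)
        pk=DrugPK("clozapine", F=0.55, CL=30.0, tau=24.0, Kp=0.03, M=326.82),
        receptors={"D1": 10000.0, "D2": 8000.0, "5HT1A": 12000.0,
                   "5HT2A": 3000.0, "M1": 2000.0},
        clinical_range=(100.0, 600.0),
        dose_step=25.0,
    ),
    DrugSpec(
        name="olanzapine",
        drug_class="antipsychotic",
        pk=DrugPK("olanzapine", F=0.60, CL=25.0, tau=24.0, Kp=0.07, M=312.44),
        # no appreciable 5-HT1A affinity
        receptors={"D1": 8000.0, "D2": 1200.0, "5HT2A": 2200.0, "M1": 4000.0},
        clinical_range=(5.0, 30.0),
        dose_step=2.5,
    ),
    DrugSpec(
        name="lamotrigine",
        drug_class="anticonvulsant",
        # near-complete absorption, CL ~ 2.5 L/hr, CSF ~ plasma
        pk=DrugPK("lamotrigine", F=0.98, CL=2.5, tau=24.0, Kp=1.0, M=256.09),
        lamotrigine=LamotrigineConstants(),
        clinical_range=(25.0, 400.0),
        dose_step=25.0,
    ),
    DrugSpec(
        name="lorazepam",
        drug_class="benzodiazepine",
        # ~91% protein bound; Kp = free CSF fraction
        pk=DrugPK("lorazepam", F=0.90, CL=4.0, tau=24.0, Kp=0.15, M=321.16),
        benzo=BenzoConstants(),
        clinical_range=(0.5, 8.0),
        dose_step=0.5,
    ),
    DrugSpec(
        name="clonazepam",
        drug_class="benzodiazepine",
        # roughly twice as potent as lorazepam clinically: half B_half
        pk=DrugPK("clonazepam", F=0.90, CL=4.5, tau=24.0, Kp=0.15, M=315.71),
        benzo=BenzoConstants(A=1.4328, B_half=36.9),
        clinical_range=(0.5, 6.0),
        dose_step=0.5,
    ),
]

#: Pre-treatment polypharmacy pool: real medication names, inert in the model.
UNCOUPLED_POOL = (
    "haloperidol", "risperidone", "quetiapine", "valproate", "lithium",
    "sertraline", "trazodone", "benztropine", "hydroxyzine", "propranolol",
)


def _placeholder_pk(name: str) -> DrugPK:
    return DrugPK(name, F=0.5, CL=10.0, tau=24.0, Kp=0.1, M=300.0)


def default_registry() -> DrugRegistry:
    drugs = {d.name: d for d in _DEFAULT_DRUGS}
    for name in UNCOUPLED_POOL:
        drugs[name] = DrugSpec(
            name=name, drug_class="uncoupled", pk=_placeholder_pk(name),
            clinical_range=(0.0, 0.0), dose_step=1.0,
        )
    return DrugRegistry(drugs=drugs, endogenous=dict(_DEFAULT_ENDOGENOUS))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def registry_to_dict(reg: DrugRegistry) -> dict:
    out: dict = {"endogenous": {}, "drugs": {}}
    for r, tone in reg.endogenous.items():
        out["endogenous"][r] = {"K_A": tone.K_A, "C_A": tone.C_A}
    for name, d in reg.drugs.items():
        rec: dict = {
            "class": d.drug_class,
            "pk": {"F": d.pk.F, "CL": d.pk.CL, "tau": d.pk.tau,
                   "Kp": d.pk.Kp, "M": d.pk.M},
            "clinical_range": list(d.clinical_range),
            "dose_step": d.dose_step,
        }
        if d.receptors:
            rec["receptors"] = dict(d.receptors)
        if d.benzo:
            rec["benzo"] = {"A": d.benzo.A, "B_half": d.benzo.B_half}
        if d.lamotrigine:
            lc = d.lamotrigine
            rec["lamotrigine"] = {"K_C_uM": lc.K_C_uM, "n": lc.n,
                                  "p_lam": lc.p_lam, "ih_slope": lc.ih_slope,
                                  "glu_slope": lc.glu_slope}
        out["drugs"][name] = rec
    return out


def registry_from_dict(d: dict) -> DrugRegistry:
    try:
        endo = {r: EndogenousReceptorTone(**v) for r, v in d["endogenous"].items()}
        drugs = {}
        for name, rec in d["drugs"].items():
            drugs[name] = DrugSpec(
                name=name,
                drug_class=rec["class"],
                pk=DrugPK(name, **rec["pk"]),
                receptors=rec.get("receptors"),
                benzo=BenzoConstants(**rec["benzo"]) if "benzo" in rec else None,
                lamotrigine=(LamotrigineConstants(**rec["lamotrigine"])
                             if "lamotrigine" in rec else None),
                clinical_range=tuple(rec.get("clinical_range", (0.0, 0.0))),
                dose_step=rec.get("dose_step", 1.0),
            )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed registry: {exc}") from exc
    return DrugRegistry(drugs=drugs, endogenous=endo)


def save_registry(reg: DrugRegistry, path) -> None:
    path = Path(path)
    d = registry_to_dict(reg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def load_registry(path) -> DrugRegistry:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return registry_from_dict(d)
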
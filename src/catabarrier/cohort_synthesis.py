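"""Synthetic patient cohort: Gaussian-copula regimens + severity scores.

Emulates the statistical structure of a residential treatment cohort:
heterogeneous pre-treatment polypharmacy narrowing to a fixed 3-class
post-treatment protocol (one of clozapine/olanzapine, lamotrigine, one
benzodiazepine), BFCRS severity ~17 before and ~4 after treatment with a
per-subject reduction confined to [9, 23].

A Gaussian copula couples the post-treatment dose variables, the
pre-treatment BFCRS score and the treatment *reduction*: latent correlated
normals are mapped through their CDF to zero-inflated dose marginals (a
presence probability plus a normal dose distribution, rounded to formulary
increments), a normal pre-score marginal, and a truncated-normal reduction
marginal confined to the observed [9, 23] window.  The post score is
pre - reduction, which keeps the retained cohort's moments at their
configured values instead of distorting them through a post-hoc window
filter.  Deliberately wide raw dose marginals produce clinically
implausible draws; plausibility filter rules then cut the raw pool
(default 700) down to a retained cohort of roughly 58.

The marginals, correlations and filter rules are documented defaults that
reproduce the target summary statistics — they are stand-ins for, not
reconstructions of, any real patient population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .errors import ConfigError
from .pharmacokinetics import Regimen
from .registry import UNCOUPLED_POOL, DrugRegistry, default_registry

BFCRS_MAX = 69  # instrument range is 0..69

POST_DRUGS = ("clozapine", "olanzapine", "lamotrigine", "lorazepam", "clonazepam")

#: copula column order: five dose-presence latents (uncorrelated with
#: severity, so that regimen-structure filters do not condition the scores),
#: five dose-value latents (severity-correlated), severity, reduction
COPULA_VARS = (
    tuple(f"{d}_presence" for d in POST_DRUGS)
    + tuple(f"{d}_dose" for d in POST_DRUGS)
    + ("bfcrs_pre", "reduction")
)


@dataclass(frozen=True)
class DoseMarginal:
    """Zero-inflated dose marginal: present with probability ``presence``,
    and if present the dose is Normal(mean, sd) rounded to ``step`` mg.

    The normal is intentionally wide (unclipped); range filters do the
    clinical truncation downstream.
    """

    mean: float
    sd: float
    presence: float
    step: float

    def __post_init__(self) -> None:
        if not 0 < self.presence <= 1:
            raise ConfigError("presence must be in (0, 1]")
        if self.sd <= 0 or self.step <= 0:
            raise ConfigError("sd and step must be > 0")


@dataclass(frozen=True)
class PreExposure:
    """Pre-treatment use of a modeled drug: probability and truncated range."""

    prob: float
    mean: float
    sd: float
    lo: float
    hi: float
    step: float


@dataclass
class GeneratorConfig:
    n_raw: int = 700
    seed: int = 0
    post_doses: Dict[str, DoseMarginal] = field(default_factory=lambda: {
        "clozapine": DoseMarginal(mean=350.0, sd=280.0, presence=0.55, step=25.0),
        "olanzapine": DoseMarginal(mean=15.0, sd=13.0, presence=0.45, step=2.5),
        "lamotrigine": DoseMarginal(mean=200.0, sd=200.0, presence=0.75, step=25.0),
        "lorazepam": DoseMarginal(mean=1.75, sd=2.1, presence=0.50, step=0.5),
        "clonazepam": DoseMarginal(mean=1.25, sd=1.4, presence=0.45, step=0.5),
    })
    bfcrs_pre_mean: float = 17.3
    bfcrs_pre_sd: float = 3.9
    #: BFCRS improvement: truncated normal on the observed window
    reduction_mean: float = 12.5
    reduction_sd: float = 3.4
    reduction_range: Tuple[float, float] = (9.0, 23.0)
    #: latent correlation between severity and every post dose value
    dose_severity_corr: float = 0.3
    #: latent correlation between severity and improvement
    pre_reduction_corr: float = 0.25
    #: latent correlation between improvement and every post dose value
    reduction_dose_corr: float = 0.3
    #: pre-treatment exposure to modeled drugs (admission regimens)
    pre_exposure: Dict[str, PreExposure] = field(default_factory=lambda: {
        "olanzapine": PreExposure(0.35, 10.0, 5.0, 2.5, 20.0, 2.5),
        "lamotrigine": PreExposure(0.25, 100.0, 50.0, 25.0, 200.0, 25.0),
        "lorazepam": PreExposure(0.15, 1.0, 0.5, 0.5, 2.0, 0.5),
        "clonazepam": PreExposure(0.12, 0.75, 0.4, 0.5, 1.5, 0.5),
    })
    #: number of additional (uncoupled) pre-treatment medications: 2 + Binomial
    extra_meds_base: int = 2
    extra_meds_n: int = 4
    extra_meds_p: float = 0.5


@dataclass
class SubjectRecord:
    subject_id: str
    regimen_pre: Regimen
    regimen_post: Regimen
    bfcrs_pre: float
    bfcrs_post: float
    personal: Optional[object] = None  # PersonalParams after calibration

    def n_medications(self, epoch: str) -> int:
        reg = self.regimen_pre if epoch == "pre" else self.regimen_post
        return sum(1 for _, d in reg.items() if d > 0)


@dataclass(frozen=True)
class FilterRule:
    """Named pure predicate on a SubjectRecord; True = keep."""

    name: str
    description: str
    predicate: Callable[[SubjectRecord], bool]

    def __call__(self, s: SubjectRecord) -> bool:
        return bool(self.predicate(s))


# ---------------------------------------------------------------------------
# copula machinery
# ---------------------------------------------------------------------------

def correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    k = len(COPULA_VARS)
    c = np.eye(k)
    i_pre = COPULA_VARS.index("bfcrs_pre")
    i_red = COPULA_VARS.index("reduction")
    for j, v in enumerate(COPULA_VARS):
        if v.endswith("_dose"):
            c[i_pre, j] = c[j, i_pre] = config.dose_severity_corr
            c[i_red, j] = c[j, i_red] = config.reduction_dose_corr
    c[i_pre, i_red] = c[i_red, i_pre] = config.pre_reduction_corr
    return c


def _cholesky(c: np.ndarray) -> np.ndarray:
    if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
        raise ConfigError("correlation matrix must be symmetric with unit diagonal")
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("correlation matrix is not positive semi-definite") from exc


def _round_step(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.asarray(x) / step) * step


def _reduction_ppf(u, config: GeneratorConfig):
    """Quantile of the truncated-normal reduction marginal."""
    lo, hi = config.reduction_range
    a = (lo - config.reduction_mean) / config.reduction_sd
    b = (hi - config.reduction_mean) / config.reduction_sd
    return truncnorm.ppf(u, a, b, loc=config.reduction_mean, scale=config.reduction_sd)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_raw(
    config: GeneratorConfig, registry: DrugRegistry | None = None
) -> List[SubjectRecord]:
    """Sample ``n_raw`` unfiltered subjects from the copula (deterministic
    per seed).  BFCRS scores are raw floats at this stage; doses are rounded
    to formulary increments."""
    registry = registry or default_registry()
    ss = np.random.SeedSequence(config.seed)
    rng_copula, rng_pre = [np.random.default_rng(s) for s in ss.spawn(2)]

    L = _cholesky(correlation_matrix(config))
    z = rng_copula.standard_normal((config.n_raw, len(COPULA_VARS))) @ L.T
    u = norm.cdf(z)

    subjects: List[SubjectRecord] = []
    uncoupled = list(UNCOUPLED_POOL)
    for i in range(config.n_raw):
        post_doses: Dict[str, float] = {}
        for j, drug in enumerate(POST_DRUGS):
            m = config.post_doses[drug]
            if u[i, j] > 1.0 - m.presence:
                dose = float(_round_step(
                    m.mean + m.sd * z[i, 5 + j], m.step))
                if dose > 0:
                    post_doses[drug] = dose

        pre_doses: Dict[str, float] = {}
        for drug, ex in config.pre_exposure.items():
            if rng_pre.random() < ex.prob:
                d = rng_pre.normal(ex.mean, ex.sd)
                d = float(_round_step(min(max(d, ex.lo), ex.hi), ex.step))
                if d > 0:
                    pre_doses[drug] = d
        n_extra = config.extra_meds_base + rng_pre.binomial(
            config.extra_meds_n, config.extra_meds_p
        )
        for name in rng_pre.choice(uncoupled, size=n_extra, replace=False):
            pre_doses[str(name)] = 1.0  # inert; dose is a placeholder

        bf_pre = config.bfcrs_pre_mean + config.bfcrs_pre_sd * z[i, 10]
        bf_post = bf_pre - _reduction_ppf(u[i, 11], config)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                regimen_pre=Regimen(pre_doses, epoch="pre"),
                regimen_post=Regimen(post_doses, epoch="post"),
                bfcrs_pre=float(bf_pre),
                bfcrs_post=float(bf_post),
            )
        )
    return subjects


def default_filter_rules(
    config: GeneratorConfig, registry: DrugRegistry | None = None
) -> List[FilterRule]:
    """Plausibility rules standing in for clinician-defined data selection."""
    registry = registry or default_registry()
    lo_r, hi_r = config.reduction_range

    def one_antipsychotic(s: SubjectRecord) -> bool:
        n = sum(1 for d in ("clozapine", "olanzapine") if s.regimen_post.doses.get(d, 0) > 0)
        return n == 1

    def one_benzo(s: SubjectRecord) -> bool:
        n = sum(1 for d in ("lorazepam", "clonazepam") if s.regimen_post.doses.get(d, 0) > 0)
        return n == 1

    def has_ltg(s: SubjectRecord) -> bool:
        return s.regimen_post.doses.get("lamotrigine", 0) > 0

    def doses_in_range(s: SubjectRecord) -> bool:
        for drug, dose in s.regimen_post.items():
            lo, hi = registry.get(drug).clinical_range
            if not lo <= dose <= hi:
                return False
        return True

    def reduction_window(s: SubjectRecord) -> bool:
        return lo_r <= s.bfcrs_pre - s.bfcrs_post <= hi_r

    def no_pre_clozapine(s: SubjectRecord) -> bool:
        # the protocol transitions patients *to* clozapine at admission
        return s.regimen_pre.doses.get("clozapine", 0) == 0

    def intensification(s: SubjectRecord) -> bool:
        # catatonia-directed medications are escalated, never tapered:
        # same-drug doses do not decrease, and the benzodiazepine load in
        # lorazepam-equivalents (clonazepam ~ 2x) does not decrease
        pre, post = s.regimen_pre.doses, s.regimen_post.doses
        for drug, dose in pre.items():
            if drug in post and post[drug] < dose:
                return False
        lrz_eq_pre = pre.get("lorazepam", 0) + 2 * pre.get("clonazepam", 0)
        lrz_eq_post = post.get("lorazepam", 0) + 2 * post.get("clonazepam", 0)
        return lrz_eq_post >= lrz_eq_pre

    return [
        FilterRule("one_antipsychotic_post",
                   "post regimen has exactly one antipsychotic", one_antipsychotic),
        FilterRule("one_benzodiazepine_post",
                   "post regimen has exactly one benzodiazepine", one_benzo),
        FilterRule("lamotrigine_post",
                   "post regimen includes lamotrigine", has_ltg),
        FilterRule("post_doses_in_clinical_range",
                   "all post doses within registry clinical ranges", doses_in_range),
        FilterRule("bfcrs_reduction_window",
                   "BFCRS reduction within the observed window", reduction_window),
        FilterRule("no_pre_clozapine",
                   "clozapine is introduced by the protocol, not present before",
                   no_pre_clozapine),
        FilterRule("treatment_intensification",
                   "catatonia-directed doses do not decrease from pre to post",
                   intensification),
    ]


def apply_filters(
    subjects: List[SubjectRecord], rules: List[FilterRule]
) -> Tuple[List[SubjectRecord], Dict]:
    """Retain subjects passing every rule; report rejections per rule
    (a subject failing several rules is counted under each)."""
    per_rule = {r.name: 0 for r in rules}
    retained = []
    for s in subjects:
        ok = True
        for r in rules:
            if not r(s):
                per_rule[r.name] += 1
                ok = False
        if ok:
            retained.append(s)
    report = {
        "n_input": len(subjects),
        "n_retained": len(retained),
        "rejections_per_rule": per_rule,
    }
    return retained, report


def assign_outcomes(
    subjects: List[SubjectRecord], config: GeneratorConfig, seed: int | None = None
) -> List[SubjectRecord]:
    """Convert raw scores to integers on the instrument scale, enforcing the
    per-subject reduction window by conditional redraw where rounding breaks
    it (deterministic per seed)."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence((seed, 0xBF))
    rng = np.random.default_rng(ss)
    lo_r, hi_r = config.reduction_range
    rho = config.pre_reduction_corr

    out = []
    for s in subjects:
        pre_i = int(round(s.bfcrs_pre))
        post_i = int(round(s.bfcrs_post))

        def ok(a: int, b: int) -> bool:
            return (lo_r <= a - b <= hi_r) and 0 <= b and a <= BFCRS_MAX

        # first resample only the reduction, keeping the subject's severity
        # (the conditional clamped redraw); fall back to redrawing the pair
        # for subjects whose severity admits no valid reduction
        z1 = (s.bfcrs_pre - config.bfcrs_pre_mean) / config.bfcrs_pre_sd
        tries = 0
        while not ok(pre_i, post_i) and tries < 300:
            z2 = rho * z1 + np.sqrt(1 - rho * rho) * rng.standard_normal()
            red = float(_reduction_ppf(norm.cdf(z2), config))
            post_i = pre_i - int(round(red))
            tries += 1
        while not ok(pre_i, post_i) and tries < 800:
            za, zb = rng.standard_normal(2)
            zb = rho * za + np.sqrt(1 - rho * rho) * zb
            pre = config.bfcrs_pre_mean + config.bfcrs_pre_sd * za
            red = float(_reduction_ppf(norm.cdf(zb), config))
            pre_i = int(round(pre))
            post_i = int(round(pre - red))
            tries += 1
        if not ok(pre_i, post_i):
            raise ConfigError("could not draw admissible BFCRS pair in 800 tries")
        out.append(replace(s, bfcrs_pre=pre_i, bfcrs_post=post_i))
    return out


def generate_cohort(
    config: GeneratorConfig | None = None, registry: DrugRegistry | None = None
) -> Tuple[List[SubjectRecord], Dict]:
    """Full pipeline: raw copula draw -> plausibility filters -> outcomes."""
    config = config or GeneratorConfig()
    registry = registry or default_registry()
    raw = generate_raw(config, registry)
    retained, report = apply_filters(raw, default_filter_rules(config, registry))
    return assign_outcomes(retained, config), report


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def cohort_to_frames(subjects: List[SubjectRecord]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    srows, rrows = [], []
    for s in subjects:
        for epoch, reg, bf in (
            ("pre", s.regimen_pre, s.bfcrs_pre),
            ("post", s.regimen_post, s.bfcrs_post),
        ):
            srows.append({"subject_id": s.subject_id, "epoch": epoch, "bfcrs": bf})
            for drug, dose in sorted(reg.items()):
                rrows.append({"subject_id": s.subject_id, "epoch": epoch,
                              "drug": drug, "dose_mg_per_day": dose})
    return pd.DataFrame(srows), pd.DataFrame(rrows)


def write_cohort(subjects: List[SubjectRecord], outdir, report: Dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subj, regs = cohort_to_frames(subjects)
    subj.to_csv(outdir / "subjects.csv", index=False)
    regs.to_csv(outdir / "regimens.csv", index=False)
    if report is not None:
        (outdir / "rejection_report.json").write_text(json.dumps(report, indent=2))


def read_cohort(indir) -> List[SubjectRecord]:
    indir = Path(indir)
    subj = pd.read_csv(indir / "subjects.csv")
    regs = pd.read_csv(indir / "regimens.csv")
    out = []
    for sid, grp in subj.groupby("subject_id", sort=True):
        scores = {r.epoch: r.bfcrs for r in grp.itertuples()}
        regimens = {}
        for epoch in ("pre", "post"):
            sel = regs[(regs.subject_id == sid) & (regs.epoch == epoch)]
            regimens[epoch] = Regimen(
                dict(zip(sel.drug, sel.dose_mg_per_day)), epoch=epoch
            )
        out.append(SubjectRecord(
            subject_id=str(sid),
            regimen_pre=regimens["pre"], regimen_post=regimens["post"],
            bfcrs_pre=scores["pre"], bfcrs_post=scores["post"],
        ))
    return out
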
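"""Cohort-level statistics: barriers, effect sizes, regressions, dose response.

The headline quantities are the per-subject barrier change under treatment,
the standardized effect sizes of the BFCRS and barrier reductions, the
affine map from barrier to BFCRS fitted through the two population means,
and per-drug dose-response curves with their linear fits.

Effect sizes are the difference in group means divided by a spread of the
data; the default spread is sqrt(s1^2 + s2^2) (the standard deviation of the
difference of independent draws), which is the convention consistent with
the clinical summary statistics this pipeline emulates.  Cohen's pooled-SD
convention is available via ``sd_mode="pooled"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .drug_coupling import CouplingConfig, apply_regimen
from .errors import DegenerateGroup, DegenerateInput, DegenerateMap, RegimeError
from .model_core import ModelParams, compute_barrier
from .pharmacokinetics import Regimen
from .registry import DrugRegistry, default_registry


@dataclass(frozen=True)
class EffectReport:
    mean_a: float
    mean_b: float
    sd: float  # the denominator spread actually used
    effect_size: float
    anova_p: float
    sd_mode: str


@dataclass(frozen=True)
class BfcrsBarrierMap:
    """Affine map BFCRS = slope * barrier + intercept through the two
    population mean points (mean barrier, mean BFCRS) pre and post."""

    slope: float
    intercept: float

    def __call__(self, barrier):
        return self.slope * np.asarray(barrier, dtype=float) + self.intercept


@dataclass(frozen=True)
class DoseResponseCurve:
    drug: str
    doses: np.ndarray
    barriers: np.ndarray
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def effect_size(group_a, group_b, sd_mode: str = "rms") -> EffectReport:
    """Standardized mean difference (a - b) with a one-way ANOVA p-value.

    ``sd_mode='rms'`` divides by sqrt(s_a^2 + s_b^2); ``'pooled'`` divides by
    the usual pooled SD.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateGroup("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if sd_mode == "rms":
        sd = float(np.sqrt(va + vb))
    elif sd_mode == "pooled":
        sd = float(np.sqrt(((a.size - 1) * va + (b.size - 1) * vb)
                           / (a.size + b.size - 2)))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if sd == 0:
        raise DegenerateGroup("zero spread in both groups")
    d = float((a.mean() - b.mean()) / sd)
    if va == 0 and vb == 0:
        p = 1.0
    else:
        p = float(stats.f_oneway(a, b).pvalue)
    return EffectReport(mean_a=float(a.mean()), mean_b=float(b.mean()),
                        sd=sd, effect_size=d, anova_p=p, sd_mode=sd_mode)


def pearson_r2(x, y) -> Tuple[float, float]:
    """Squared Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need n >= 3 paired values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateInput("constant input variable")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


# ---------------------------------------------------------------------------
# barriers over a cohort
# ---------------------------------------------------------------------------

def subject_barriers(
    subject,
    registry: DrugRegistry,
    cfg: CouplingConfig | None = None,
    p0: ModelParams | None = None,
) -> Tuple[float, float]:
    """(B_pre, B_post) for one subject's regimens on baseline parameters."""
    p0 = p0 or ModelParams.baseline()
    cfg = cfg or CouplingConfig()
    out = []
    for reg in (subject.regimen_pre, subject.regimen_post):
        try:
            p = apply_regimen(p0, reg, registry, cfg)
            out.append(compute_barrier(p).B)
        except RegimeError as exc:
            raise RegimeError(f"subject {subject.subject_id}: {exc}") from exc
    return out[0], out[1]


def cohort_barriers(
    cohort: Sequence,
    registry: DrugRegistry | None = None,
    cfg: CouplingConfig | None = None,
    p0: ModelParams | None = None,
) -> pd.DataFrame:
    """Table (subject_id, B_pre, B_post, delta_B) over the cohort."""
    registry = registry or default_registry()
    rows = []
    for s in cohort:
        b_pre, b_post = subject_barriers(s, registry, cfg, p0)
        rows.append({"subject_id": s.subject_id, "B_pre": b_pre,
                     "B_post": b_post, "delta_B": b_pre - b_post})
    return pd.DataFrame(rows)


def fit_bfcrs_map(
    barriers: pd.DataFrame, cohort: Sequence
) -> BfcrsBarrierMap:
    """Two-point affine map through (mean B, mean BFCRS) pre and post."""
    b_pre = float(barriers["B_pre"].mean())
    b_post = float(barriers["B_post"].mean())
    s_pre = float(np.mean([s.bfcrs_pre for s in cohort]))
    s_post = float(np.mean([s.bfcrs_post for s in cohort]))
    if abs(b_pre - b_post) < 1e-12:
        raise DegenerateMap("mean barriers coincide")
    slope = (s_pre - s_post) / (b_pre - b_post)
    return BfcrsBarrierMap(slope=slope, intercept=s_pre - slope * b_pre)


def bfcrs_barrier_regression(
    barriers: pd.DataFrame, cohort: Sequence, mode: str = "pooled"
) -> Tuple[float, float]:
    """r^2 between BFCRS and barrier.

    ``mode='pooled'`` pools the pre and post points of every subject
    (2n pairs); ``mode='change'`` regresses the per-subject changes.
    """
    pre = np.array([s.bfcrs_pre for s in cohort], dtype=float)
    post = np.array([s.bfcrs_post for s in cohort], dtype=float)
    if mode == "pooled":
        x = np.concatenate([barriers["B_pre"], barriers["B_post"]])
        y = np.concatenate([pre, post])
    elif mode == "change":
        x = barriers["delta_B"].to_numpy()
        y = pre - post
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pearson_r2(x, y)


# ---------------------------------------------------------------------------
# dose response and combinations
# ---------------------------------------------------------------------------

def dose_response(
    drug: str,
    dose_grid: Iterable[float] | None = None,
    registry: DrugRegistry | None = None,
    cfg: CouplingConfig | None = None,
    p0: ModelParams | None = None,
    n_points: int = 12,
) -> DoseResponseCurve:
    """Barrier across a dose grid for one drug alone on baseline parameters,
    with a linear fit.  Default grid: evenly spaced over the registry's
    clinical range."""
    registry = registry or default_registry()
    p0 = p0 or ModelParams.baseline()
    spec = registry.get(drug)
    if dose_grid is None:
        lo, hi = spec.clinical_range
        dose_grid = np.linspace(lo, hi, n_points)
    doses = np.asarray(list(dose_grid), dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    barriers = []
    for d in doses:
        p = apply_regimen(p0, Regimen({drug: float(d)}), registry, cfg)
        barriers.append(compute_barrier(p).B)
    barriers = np.asarray(barriers)
    fit = stats.linregress(doses, barriers)
    return DoseResponseCurve(
        drug=drug, doses=doses, barriers=barriers,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def combination_grid(
    meds: Sequence[Tuple[str, float]],
    registry: DrugRegistry | None = None,
    cfg: CouplingConfig | None = None,
    p0: ModelParams | None = None,
    bfcrs_map: BfcrsBarrierMap | None = None,
) -> pd.DataFrame:
    """Barrier (and optionally mapped BFCRS) for every subset of ``meds``."""
    if len(meds) > 5:
        raise ValueError("at most 5 drugs in a combination grid")
    registry = registry or default_registry()
    p0 = p0 or ModelParams.baseline()
    b0 = compute_barrier(p0).B
    rows = []
    for k in range(len(meds) + 1):
        for subset in itertools.combinations(meds, k):
            doses = {d: v for d, v in subset}
            p = apply_regimen(p0, Regimen(doses), registry, cfg)
            b = compute_barrier(p).B
            row = {"drugs": "+".join(d for d, _ in subset) or "(none)",
                   "n_drugs": len(subset), "barrier": b, "delta_B": b0 - b}
            if bfcrs_map is not None:
                row["predicted_bfcrs"] = float(bfcrs_map(b))
            rows.append(row)
    return pd.DataFrame(rows)
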
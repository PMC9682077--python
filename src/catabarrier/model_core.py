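"""Bistable Wilson-Cowan cortical circuit: dynamics, fixed points, barrier.

The model is two coupled rate equations for an inhibitory population (``x0``,
parvalbumin-positive interneurons) and an excitatory population (``x1``,
pyramidal cells)::

    dx0/dt = -x0 + S0(w01*x1 - w00*x0)
    dx1/dt = -x1 + S1(w11*x1 - w10*x0)

with the rest-normalized logistic rate function

    Sa(x) = sigma(mu_a*(x - theta_a)) - sigma(-mu_a*theta_a),

so that the quiescent state (0, 0) is an exact fixed point.  Weight indices
are postsynaptic-first (``w01`` is the excitatory drive onto the inhibitory
population).  In the regime studied here the circuit has exactly three fixed
points: a low-rate attractor at the origin, a high-rate attractor
(x1 ~ 0.88 at baseline), and a saddle whose stable manifold separates the two
basins.  Catatonia is modeled as over-persistence of the high-rate state; the
scalar "barrier" B quantifies how hard it is to escape that state.

B is the cumulative sum of dx1/dt over a lattice of evenly spaced points on
the x0-nullcline between the high-rate fixed point and the saddle (the
discrete line integral of the excitatory rate gradient, i.e. the depth of the
high-rate well of the effective 1-D potential).  The sum is scaled by
``100 / n_lattice`` so that its value is stable under lattice refinement and
coincides with the plain 100-point sum at the default resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import RegimeError, RootNotFound

PARAM_NAMES = ("mu0", "mu1", "theta0", "theta1", "w00", "w01", "w10", "w11")

#: x0 search bracket for the x0-nullcline root (rates live in [0, 1]).
_X0_BRACKET = (0.0, 1.5)
#: duplicate-merge tolerance for fixed points (both coordinates).
_DEDUP_TOL = 1e-4


@dataclass(frozen=True)
class ModelParams:
    """The eight parameters of one cortical circuit instance.

    ``mu``/``theta`` are slope and threshold of each population's rate
    function; ``wab`` is the synaptic weight onto population ``a`` from
    population ``b`` (0 = inhibitory, 1 = excitatory).  All dimensionless.
    """

    mu0: float = 1.0
    mu1: float = 1.2
    theta0: float = 4.0
    theta1: float = 2.8
    w00: float = 9.0
    w01: float = 13.0
    w10: float = 4.0
    w11: float = 8.65

    def __post_init__(self) -> None:
        for name in ("mu0", "mu1", "w00", "w01", "w10", "w11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def baseline(cls) -> "ModelParams":
        return cls()

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})

    def replace(self, **kw: float) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)


class RateState(NamedTuple):
    """Population rates as fractions of maximum, (inhibitory, excitatory)."""

    x0: float
    x1: float


@dataclass(frozen=True)
class FixedPoint:
    state: RateState
    kind: str  # stable_low | stable_high | saddle | unstable
    eigenvalues: tuple

    @property
    def is_stable(self) -> bool:
        return self.kind.startswith("stable")


@dataclass(frozen=True)
class BarrierResult:
    """Barrier height with the lattice and fixed points that produced it."""

    B: float
    raw_sum: float  # plain cumulative sum of dx1/dt at the actual lattice
    lattice: tuple  # RateState points, high-rate fixed point -> saddle
    fixed_points: tuple  # (low, saddle, high)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-step additive Gaussian perturbation of both populations."""

    mean: float = 0.0
    std: float = 0.19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("noise std must be >= 0")


@dataclass
class SimulationTrace:
    times: np.ndarray
    states: np.ndarray  # shape (n, 2): columns x0, x1
    transition_time: float | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "x0": self.states[:, 0], "x1": self.states[:, 1]}
        )


# ---------------------------------------------------------------------------
# rate function and flow field
# ---------------------------------------------------------------------------

def spike_rate(x, mu: float, theta: float):
    """Logistic spike-probability function 1 / (1 + exp(-mu*(x - theta)))."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return 1.0 / (1.0 + np.exp(-mu * (np.asarray(x, dtype=float) - theta)))


def rest_rate(mu: float, theta: float) -> float:
    """Value of the logistic at zero input; subtracted so S(0) = 0."""
    return float(spike_rate(0.0, mu, theta))


def _S(x, mu: float, theta: float):
    return spike_rate(x, mu, theta) - rest_rate(mu, theta)


def derivatives(state, p: ModelParams):
    """Flow field (dx0/dt, dx1/dt); accepts scalars or arrays."""
    x0, x1 = np.asarray(state[0], dtype=float), np.asarray(state[1], dtype=float)
    d0 = -x0 + _S(p.w01 * x1 - p.w00 * x0, p.mu0, p.theta0)
    d1 = -x1 + _S(p.w11 * x1 - p.w10 * x0, p.mu1, p.theta1)
    return d0, d1


def jacobian(state, p: ModelParams) -> np.ndarray:
    x0, x1 = state
    s0 = spike_rate(p.w01 * x1 - p.w00 * x0, p.mu0, p.theta0)
    s1 = spike_rate(p.w11 * x1 - p.w10 * x0, p.mu1, p.theta1)
    f0p = p.mu0 * s0 * (1.0 - s0)
    f1p = p.mu1 * s1 * (1.0 - s1)
    return np.array(
        [
            [-1.0 - p.w00 * f0p, p.w01 * f0p],
            [-p.w10 * f1p, -1.0 + p.w11 * f1p],
        ]
    )


# ---------------------------------------------------------------------------
# nullcline and fixed points
# ---------------------------------------------------------------------------

def x0_nullcline(p: ModelParams, x1_values) -> np.ndarray:
    """Solve x0 = S0(w01*x1 - w00*x0) for each x1 by vectorized bisection.

    The right-hand side is strictly decreasing in x0, so the root is unique;
    residuals are driven below 1e-8.
    """
    x1 = np.atleast_1d(np.asarray(x1_values, dtype=float))

    def g(x0):
        return -x0 + _S(p.w01 * x1 - p.w00 * x0, p.mu0, p.theta0)

    lo = np.full_like(x1, _X0_BRACKET[0])
    hi = np.full_like(x1, _X0_BRACKET[1])
    glo = g(lo)
    if np.any(glo < -1e-12) or np.any(g(hi) > 1e-12):
        raise RootNotFound("x0-nullcline root not bracketed in [0, 1.5]")
    for _ in range(52):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        take = gm > 0
        lo = np.where(take, mid, lo)
        hi = np.where(take, hi, mid)
    root = 0.5 * (lo + hi)
    if np.any(np.abs(g(root)) > 1e-8):
        raise RootNotFound("x0-nullcline residual above 1e-8")
    if np.isscalar(x1_values) or np.ndim(x1_values) == 0:
        return float(root[0])
    return root


def _newton_refine(seed, p: ModelParams, max_iter: int = 40):
    """Damped Newton iteration on the full 2-D system from a scan seed."""
    x = np.array(seed, dtype=float)
    for _ in range(max_iter):
        f = np.array(derivatives((x[0], x[1]), p), dtype=float)
        if np.max(np.abs(f)) < 1e-13:
            return RateState(float(x[0]), float(x[1]))
        try:
            step = np.linalg.solve(jacobian(x, p), f)
        except np.linalg.LinAlgError:
            return None
        scale = 1.0
        for _ in range(6):
            xn = x - scale * step
            fn = np.array(derivatives((xn[0], xn[1]), p), dtype=float)
            if np.sum(fn * fn) < np.sum(f * f):
                x = xn
                break
            scale *= 0.5
        else:
            return None
        if not (-0.2 <= x[0] <= 1.3 and -0.2 <= x[1] <= 1.3):
            return None
    return None


def _classify(state: RateState, p: ModelParams, x1_rank: str) -> FixedPoint:
    eig = np.linalg.eigvals(jacobian(state, p))
    re = np.real(eig)
    if np.all(re < 0):
        kind = f"stable_{x1_rank}"
    elif re[0] * re[1] < 0:
        kind = "saddle"
    else:
        kind = "unstable"
    return FixedPoint(state=state, kind=kind, eigenvalues=tuple(eig))


def find_fixed_points(
    p: ModelParams, grid_size: int = 512, require_bistable: bool = False
) -> list:
    """All fixed points in the unit box, classified by Jacobian eigenvalues.

    Every fixed point lies on the x0-nullcline, so it suffices to scan
    dx1/dt along that curve for sign changes and refine each bracket with
    Brent's method.  Duplicates within 1e-4 in both coordinates are merged.
    """
    xs = np.linspace(0.0, 1.0, grid_size)
    x0n = x0_nullcline(p, xs)
    g = derivatives((x0n, xs), p)[1]

    seeds: list[tuple] = []
    for i in range(grid_size - 1):
        if abs(g[i]) < 1e-13:
            seeds.append((x0n[i], xs[i]))
        elif g[i] * g[i + 1] < 0:
            w = abs(g[i]) / (abs(g[i]) + abs(g[i + 1]))
            seeds.append(((1 - w) * x0n[i] + w * x0n[i + 1],
                          (1 - w) * xs[i] + w * xs[i + 1]))
    if abs(g[-1]) < 1e-13:
        seeds.append((x0n[-1], xs[-1]))

    states: list[RateState] = []
    for seed in seeds:
        st = _newton_refine(seed, p)
        if st is None:  # fall back to bracketed search on the nullcline
            def g_scalar(x1: float) -> float:
                return float(derivatives((x0_nullcline(p, float(x1)), x1), p)[1])

            i = int(np.clip(np.searchsorted(xs, seed[1]) - 1, 0, grid_size - 2))
            r = brentq(g_scalar, xs[i], xs[i + 1], xtol=1e-12)
            st = RateState(x0=float(x0_nullcline(p, float(r))), x1=float(r))
        if not any(
            abs(st.x0 - s.x0) < _DEDUP_TOL and abs(st.x1 - s.x1) < _DEDUP_TOL
            for s in states
        ):
            states.append(st)
    states.sort(key=lambda s: s.x1)

    fps: list[FixedPoint] = []
    for i, st in enumerate(states):
        rank = "low" if i == 0 else ("high" if i == len(states) - 1 else "mid")
        fps.append(_classify(st, p, rank))
    if require_bistable and len(fps) != 3:
        raise RegimeError(
            f"expected 3 fixed points in the bistable regime, found {len(fps)}"
        )
    return fps


def bistable_triple(p: ModelParams) -> tuple:
    """Return (low, saddle, high) fixed points or raise RegimeError."""
    fps = find_fixed_points(p, require_bistable=True)
    low, mid, high = fps
    if not (low.is_stable and high.is_stable and mid.kind == "saddle"):
        raise RegimeError(
            "fixed-point kinds are not (stable, saddle, stable): "
            + ", ".join(f.kind for f in fps)
        )
    return low, mid, high


# ---------------------------------------------------------------------------
# barrier
# ---------------------------------------------------------------------------

def compute_barrier(p: ModelParams, n_lattice: int = 100) -> BarrierResult:
    """Barrier of the high-rate basin.

    The lattice is ``n_lattice`` evenly spaced x1 values from the high-rate
    fixed point down to the saddle, lifted onto the x0-nullcline.  The
    reported B is the cumulative sum of dx1/dt over the lattice scaled by
    ``100 / n_lattice`` (equal to the plain sum at the default resolution,
    stable under refinement).
    """
    if n_lattice < 2:
        raise ValueError("n_lattice must be >= 2")
    low, saddle, high = bistable_triple(p)
    x1s = np.linspace(high.state.x1, saddle.state.x1, n_lattice)
    x0s = x0_nullcline(p, x1s)
    d1 = derivatives((x0s, x1s), p)[1]
    raw = float(np.sum(d1))
    B = max(raw * (100.0 / n_lattice), 0.0)
    lattice = tuple(RateState(float(a), float(b)) for a, b in zip(x0s, x1s))
    return BarrierResult(B=B, raw_sum=raw, lattice=lattice, fixed_points=(low, saddle, high))


def minimal_escape_perturbation(
    p: ModelParams, tol: float = 1e-4, dt: float = 0.05, t_max: float = 400.0
) -> float:
    """Smallest instantaneous downward x1 kick from the high-rate fixed point
    that escapes its basin (noiseless integration endpoint test), by bisection.

    Independent escape-difficulty measure used to validate that the barrier
    statistic ranks parameter sets correctly.
    """
    low, saddle, high = bistable_triple(p)

    def escapes(delta: float) -> bool:
        x0, x1 = high.state.x0, high.state.x1 - delta
        n = int(t_max / dt)
        for _ in range(n):
            d0, d1 = derivatives((x0, x1), p)
            x0 += dt * float(d0)
            x1 += dt * float(d1)
        return x1 < saddle.state.x1

    lo, hi = 0.0, high.state.x1
    if not escapes(hi):
        raise RegimeError("full kick does not escape; basins malformed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if escapes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def simulate(
    p: ModelParams,
    init: RateState,
    noise: NoiseSpec,
    t_max: float = 1000.0,
    dt: float = 0.1,
    low_threshold: float = 0.2,
    sustain_steps: int = 10,
) -> SimulationTrace:
    """Forward-Euler simulation with an independent Gaussian perturbation
    added to each population at every step (no sqrt(dt) scaling; the step
    size is part of the noise model).  Rates are clipped to [0, 1].

    ``transition_time`` is the first time x1 stays below ``low_threshold``
    for ``sustain_steps`` consecutive steps (decay of the high-rate state).
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be > 0")
    n = int(round(t_max / dt))
    rng = np.random.default_rng(noise.seed)
    kicks = rng.normal(noise.mean, noise.std, size=(n, 2)) if noise.std > 0 else None
    if kicks is None and noise.mean != 0.0:
        kicks = np.full((n, 2), noise.mean)

    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 2))
    states[0] = (init.x0, init.x1)
    x0, x1 = float(init.x0), float(init.x1)
    below = 0
    transition_time = None
    for i in range(n):
        d0, d1 = derivatives((x0, x1), p)
        x0 += dt * float(d0)
        x1 += dt * float(d1)
        if kicks is not None:
            x0 += kicks[i, 0]
            x1 += kicks[i, 1]
        x0 = min(max(x0, 0.0), 1.0)
        x1 = min(max(x1, 0.0), 1.0)
        states[i + 1] = (x0, x1)
        if x1 < low_threshold:
            below += 1
            if below >= sustain_steps and transition_time is None:
                transition_time = times[i + 1]
        else:
            below = 0
    return SimulationTrace(times=times, states=states, transition_time=transition_time)


# ---------------------------------------------------------------------------
# parameter-set I/O (flat key-value YAML/JSON)
# ---------------------------------------------------------------------------

def save_params(p: ModelParams, path) -> None:
    path = Path(path)
    d = p.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def load_params(path) -> ModelParams:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelParams.from_dict(d)
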
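"""Parameter estimation by weighted least squares and particle swarm.

The objective is the sum of squared sigma-weighted residuals

    f(p) = sum_i ((x_i - y_i(p)) / sigma_i)^2

over steady-state and time-course observations, minimized under box
constraints on the parameter classes (Km in [1e-4, 1e3] mM, Vmax in
[1e-2, 1e3] mM/s, Keq in [1e-4, 1e6]) by a reflective-boundary particle
swarm.  A simulation failure inside the objective returns a large finite
penalty (plus a distance-to-reference term that keeps the swarm moving),
never an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import KineticModel

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationDataset",
    "ParameterSpec",
    "objective",
    "fit",
    "recovery_report",
    "particle_swarm",
    "PARAMETER_BOUNDS",
]

#: Box constraints per parameter class (printed constraint vector).
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "Km": (1e-4, 1e3),    # mM
    "Vmax": (1e-2, 1e3),  # mM/s
    "Keq": (1e-4, 1e6),   # dimensionless
}

# must dominate any finite weighted SSE (tight sigmas make bad-but-feasible
# fits reach ~1e25)
_FAILURE_PENALTY = 1e30


@dataclass(frozen=True)
class DataPoint:
    """One observation: a flux or concentration, at steady state or a time."""

    observable: str        # reaction id (flux) or species id (concentration)
    kind: str              # "flux" | "concentration"
    value: float
    sigma: float
    time: float | None = None  # None => steady state
    condition: str = "reference"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0 for observable '{self.observable}'")


@dataclass
class CalibrationDataset:
    points: list[DataPoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("empty calibration dataset")

    @property
    def n(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.observable, p.kind, p.condition,
                 "" if p.time is None else p.time, p.value, p.sigma)
                for p in self.points
            ],
            columns=["observable", "kind", "condition", "time", "value", "sigma"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationDataset":
        pts = []
        for _, r in df.iterrows():
            t = r["time"]
            time = None if (t == "" or pd.isna(t)) else float(t)
            pts.append(
                DataPoint(
                    observable=str(r["observable"]), kind=str(r["kind"]),
                    value=float(r["value"]), sigma=float(r["sigma"]),
                    time=time, condition=str(r["condition"]),
                )
            )
        return cls(pts)


@dataclass
class ParameterSpec:
    """Free parameters (namespaced '<reaction>.<name>') with box bounds."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def for_model(cls, model: KineticModel, free: Sequence[str]) -> "ParameterSpec":
        """Bounds assigned by parameter class (from the name's last token)."""
        lo, hi = [], []
        for name in free:
            if name not in model.parameter_names:
                raise KeyError(f"unknown parameter '{name}'")
            cls_key = _classify(name)
            b = PARAMETER_BOUNDS.get(cls_key)
            if b is None:
                # parameters outside the stated classes keep a generous box
                b = (1e-6, 1e6)
            lo.append(b[0])
            hi.append(b[1])
        return cls(names=list(free), lower=np.array(lo), upper=np.array(hi))

    def validate(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")


def _classify(name: str) -> str:
    leaf = name.split(".")[-1]
    if leaf == "Vmax":
        return "Vmax"
    if leaf == "Keq":
        return "Keq"
    if leaf.startswith(("Km", "Ki", "Ka", "K")):
        return "Km"
    return leaf


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _predict(model: KineticModel, params: np.ndarray, dataset: CalibrationDataset):
    """Simulated observables for every data point (grouped by condition)."""
    preds = np.empty(dataset.n)
    # steady-state points
    ss_idx = [i for i, p in enumerate(dataset.points) if p.time is None]
    tc_idx = [i for i, p in enumerate(dataset.points) if p.time is not None]
    if ss_idx:
        ss = model.steady_state(parameters=params, eval_budget=20_000)
        if not ss.converged:
            raise RuntimeError("steady state failed")
        for i in ss_idx:
            p = dataset.points[i]
            preds[i] = ss.flux(p.observable) if p.kind == "flux" else ss.concentration(p.observable)
    if tc_idx:
        times = sorted({dataset.points[i].time for i in tc_idx})
        grid = np.concatenate([[0.0], np.asarray(times, float)])
        if grid[1] == 0.0:
            grid = grid[1:]
        traj = model.simulate(grid, parameters=params)
        for i in tc_idx:
            p = dataset.points[i]
            if p.kind != "concentration":
                raise ValueError("time-course observables must be concentrations")
            ti = int(np.argmin(np.abs(traj.t - p.time)))
            preds[i] = traj.series(p.observable)[ti]
    return preds


def objective(
    p: np.ndarray,
    model: KineticModel,
    dataset: CalibrationDataset,
    spec: ParameterSpec,
) -> float:
    """f(p) = sum_i ((x_i - y_i(p)) / sigma_i)^2; failures -> large penalty."""
    full = model.parameter_vector
    names = list(model.parameter_names)
    for name, value in zip(spec.names, p):
        full[names.index(name)] = value
    try:
        preds = _predict(model, full, dataset)
    except Exception:
        # keep the landscape informative where simulation fails
        mid = (spec.lower + spec.upper) / 2
        span = spec.upper - spec.lower
        return _FAILURE_PENALTY + float(np.sum(((p - mid) / span) ** 2))
    res = [
        (pt.value - y) / pt.sigma for pt, y in zip(dataset.points, preds)
    ]
    return float(np.sum(np.square(res)))


# ---------------------------------------------------------------------------
# Particle swarm
# ---------------------------------------------------------------------------

def particle_swarm(
    func: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    n_particles: int = 50,
    iterations: int = 100,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    seed=None,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Box-constrained PSO with reflective bound handling.

    Returns (best position, best value, best-value trace).  Deterministic
    under a fixed seed.  Degenerate boxes (lower == upper) short-circuit.
    ``init`` rows replace the first initial particles (known good starts).
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if np.any(lower > upper):
        raise ValueError("lower > upper")
    if np.all(lower == upper):
        val = func(lower.copy())
        return lower.copy(), float(val), [float(val)]
    rng = np.random.default_rng(seed)
    dim = len(lower)
    span = upper - lower
    x = lower + span * rng.uniform(size=(n_particles, dim))
    if init is not None:
        init = np.atleast_2d(np.clip(init, lower, upper))
        x[: len(init)] = init
    v = 0.1 * span * rng.uniform(-1, 1, size=(n_particles, dim))
    pbest = x.copy()
    pval = np.array([func(xi) for xi in x])
    g = int(np.argmin(pval))
    gbest, gval = pbest[g].copy(), float(pval[g])
    trace = [gval]
    for _ in range(iterations):
        r1 = rng.uniform(size=(n_particles, dim))
        r2 = rng.uniform(size=(n_particles, dim))
        v = inertia * v + cognitive * r1 * (pbest - x) + social * r2 * (gbest - x)
        x = x + v
        # reflective bounds
        over = x > upper
        under = x < lower
        x = np.where(over, 2 * upper - x, x)
        x = np.where(under, 2 * lower - x, x)
        v = np.where(over | under, -v, v)
        x = np.clip(x, lower, upper)  # double reflections on tiny boxes
        vals = np.array([func(xi) for xi in x])
        better = vals < pval
        pbest[better] = x[better]
        pval[better] = vals[better]
        g = int(np.argmin(pval))
        if pval[g] < gval:
            gbest, gval = pbest[g].copy(), float(pval[g])
        trace.append(gval)
    return gbest, gval, trace


@dataclass
class FitResult:
    parameters: dict[str, float]
    objective: float
    trace: list[float]
    seed: int | None
    n_evaluations: int


def fit(
    model: KineticModel,
    dataset: CalibrationDataset,
    spec: ParameterSpec,
    n_particles: int = 50,
    iterations: int = 100,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    seed: int | None = None,
    log_scale: bool = True,
) -> FitResult:
    """Global fit of the free parameters by particle swarm.

    With ``log_scale`` (default) the swarm explores log10 parameter space,
    which suits kinetic constants whose admissible ranges span several
    decades; bounds are respected either way.
    """
    spec.validate()
    evals = [0]

    if log_scale:
        if np.any(spec.lower <= 0):
            raise ValueError("log-scale search requires positive lower bounds")
        lo, hi = np.log10(spec.lower), np.log10(spec.upper)
        decode = lambda z: 10**z
    else:
        lo, hi = spec.lower, spec.upper
        decode = lambda z: z

    def f(z):
        evals[0] += 1
        return objective(decode(z), model, dataset, spec)

    best, val, trace = particle_swarm(
        f, lo, hi,
        n_particles=n_particles, iterations=iterations,
        inertia=inertia, cognitive=cognitive, social=social, seed=seed,
    )
    if val >= _FAILURE_PENALTY:
        raise RuntimeError("no feasible evaluation within the budget")
    return FitResult(
        parameters=dict(zip(spec.names, decode(best))),
        objective=val,
        trace=trace,
        seed=seed,
        n_evaluations=evals[0],
    )


def recovery_report(
    true_p: Mapping[str, float],
    fitted_p: Mapping[str, float],
    spec: ParameterSpec,
    bound_tol: float = 1e-3,
) -> pd.DataFrame:
    """Per-parameter relative error and bound-hit flags.

    A fitted value at (or numerically against) a box bound marks the
    parameter as a non-identifiability suspect.
    """
    if set(true_p) != set(fitted_p):
        raise ValueError("parameter sets differ")
    rows = []
    for name, lo, hi in zip(spec.names, spec.lower, spec.upper):
        t, f_ = true_p[name], fitted_p[name]
        rel = abs(f_ - t) / abs(t) if t != 0 else np.inf
        # bound proximity judged on the log scale (bounds span decades)
        at_bound = False
        if hi > lo and f_ > 0 and lo > 0:
            width = np.log10(hi) - np.log10(lo)
            at_bound = (
                np.log10(f_ / lo) <= bound_tol * width
                or np.log10(hi / f_) <= bound_tol * width
            )
        rows.append((name, t, f_, rel, bool(at_bound)))
    return pd.DataFrame(
        rows, columns=["parameter", "true", "fitted", "relative_error", "at_bound"]
    )
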
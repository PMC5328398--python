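"""Solution-space exploration.

Two complementary samplers probe what the metabolic network can do:

* the *kinetic* solution space — steady states reachable by the full kinetic
  model when enzyme capacities (Vmax) are drawn log-uniformly over two
  orders of magnitude around the reference, simulated under excess glucose;
* the *stoichiometric* solution space — the flux polytope
  {v : S v = 0, lb <= v <= ub} of the same network stripped of all kinetics,
  sampled approximately uniformly by hit-and-run over its null-space
  parameterization.

Boundaries of both spaces over a pair of physiological variables are
estimated by linear programming (stoichiometric side, exact up to LP
tolerance) and by a population-based search over enzyme levels (kinetic
side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import linprog

from .model import KineticModel, SteadyState
from .ratelaws import OXPHOS_FORMS

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeSample",
    "EnsembleResult",
    "StoichiometricModel",
    "BoundarySet",
    "sample_enzyme_levels",
    "ensemble_steady_states",
    "to_stoichiometric",
    "sample_flux_space",
    "kinetic_boundaries",
    "stoichiometric_boundaries",
]


@dataclass(frozen=True)
class EnzymeSample:
    """Per-reaction Vmax scale factors (log-uniform in [lo, hi])."""

    factors: np.ndarray
    stream: int = 0


@dataclass
class EnsembleResult:
    """Steady states for an ensemble of random enzyme levels."""

    samples: list[EnzymeSample]
    states: list[SteadyState]
    converged: np.ndarray  # bool per sample
    model: KineticModel
    condition: str = "excess_glucose"

    @property
    def convergence_rate(self) -> float:
        return float(np.mean(self.converged)) if len(self.converged) else 0.0

    def converged_states(self) -> list[SteadyState]:
        return [s for s, ok in zip(self.states, self.converged) if ok]

    def converged_samples(self) -> list[EnzymeSample]:
        return [s for s, ok in zip(self.samples, self.converged) if ok]

    def flux_table(self) -> pd.DataFrame:
        """One row per converged state, one column per reaction (mM/s)."""
        rows = [s.fluxes for s in self.converged_states()]
        return pd.DataFrame(rows, columns=list(self.model.reaction_ids))

    def concentration_table(self) -> pd.DataFrame:
        rows = [s.concentrations for s in self.converged_states()]
        return pd.DataFrame(rows, columns=list(self.model.species_ids))


@dataclass
class StoichiometricModel:
    """Constraint-only version of a kinetic model: S v = 0, lb <= v <= ub."""

    S: np.ndarray  # internal species x reactions
    lower: np.ndarray
    upper: np.ndarray
    reaction_ids: tuple[str, ...]
    species_ids: tuple[str, ...]

    def check(self, v: np.ndarray, tol: float = 1e-9) -> bool:
        return bool(
            np.all(v >= self.lower - tol)
            and np.all(v <= self.upper + tol)
            and np.max(np.abs(self.S @ v)) <= tol
        )


@dataclass
class BoundarySet:
    """Envelope of a 2-D variable pair: per grid value of x, [y_min, y_max]."""

    variable_pair: tuple[str, str]
    table: pd.DataFrame  # columns: x, y_min, y_max, feasible
    source: str  # "kinetic" | "stoichiometric"


# ---------------------------------------------------------------------------
# Kinetic ensemble
# ---------------------------------------------------------------------------

def sample_enzyme_levels(
    model: KineticModel,
    n: int,
    lo: float = 0.1,
    hi: float = 10.0,
    seed: int | None = None,
) -> list[EnzymeSample]:
    """Independent per-reaction Vmax factors, log10-uniform on [lo, hi].

    The log-uniform draw samples each order of magnitude in equal
    proportion.  Deterministic for a fixed seed; per-sample substreams make
    the draw independent of evaluation order.
    """
    if not (0 < lo <= hi):
        raise ValueError(f"invalid bounds lo={lo}, hi={hi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        f = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=len(model.reactions))
        out.append(EnzymeSample(factors=f, stream=i))
    return out


def ensemble_steady_states(
    model: KineticModel,
    samples: Sequence[EnzymeSample],
    glucose_mM: float | None = None,
    eval_budget: int = 40_000,
    progress: Callable[[int, int], None] | None = None,
) -> EnsembleResult:
    """Steady state for every enzyme sample; failures flagged, never dropped.

    ``glucose_mM`` clamps extracellular glucose (excess-glucose condition);
    pass None if the model is already conditioned.  Every solve starts from
    the condition's reference steady state: the model is multistable, so the
    reached basin depends on the initial state, and starting each sample
    from the previous sample's solution would make the ensemble a correlated
    chain whose statistics depend on sample order.  The reference start is
    also the physical protocol (enzyme levels change in a cell at the
    reference state).
    """
    work = model
    if glucose_mM is not None:
        work = model.with_boundary("GLC_env", glucose_mM)
    base = work.steady_state()
    warm_ref = base.concentrations
    states, converged = [], []
    for i, sample in enumerate(samples):
        ss = work.steady_state(warm_ref, vmax_scale=sample.factors,
                               eval_budget=eval_budget)
        states.append(ss)
        converged.append(ss.converged)
        if progress is not None:
            progress(i + 1, len(samples))
    conv = np.array(converged)
    if len(samples) >= 10 and conv.mean() < 0.1:
        raise RuntimeError(
            f"ensemble failure: only {conv.sum()}/{len(samples)} samples converged"
        )
    result = EnsembleResult(
        samples=list(samples), states=states, converged=conv, model=work
    )
    logger.info("ensemble: %d/%d converged", int(conv.sum()), len(samples))
    return result


# ---------------------------------------------------------------------------
# Stoichiometric model and uniform flux sampling
# ---------------------------------------------------------------------------

_REVERSIBLE_FORMS = {
    "mass_action_reversible",
    "reversible_michaelis_menten",
    "convenience_reversible",
    *OXPHOS_FORMS,
    "ndhi",
    "ndh2",
    "sqr",
    "cytbo",
    "atp_syn",
}


def to_stoichiometric(
    model: KineticModel,
    flux_cap: Mapping[str, float] | float = 1.0,
) -> StoichiometricModel:
    """Strip the kinetics: keep S over internal (non-boundary) species.

    Reversibility is inferred from the rate-law form: reversible forms get
    symmetric bounds, irreversible ones a zero lower bound.  ``flux_cap``
    sets |v| <= cap (mM/s), either one global cap or per reaction; any
    kinetic steady-state flux vector within the caps satisfies the
    constraints by construction.
    """
    if len(model.reactions) == 0:
        raise ValueError("empty model")
    internal = [s for s in model.species if not s.is_boundary]
    sidx = {s.id: i for i, s in enumerate(model.species)}
    S_full = model.stoichiometric_matrix
    rows = [sidx[s.id] for s in internal]
    S = S_full[rows, :]
    n_r = len(model.reactions)
    caps = (
        np.full(n_r, float(flux_cap))
        if np.isscalar(flux_cap)
        else np.array([flux_cap.get(r.id, 1.0) for r in model.reactions])
    )
    lower = np.empty(n_r)
    upper = caps.copy()
    for j, rxn in enumerate(model.reactions):
        lower[j] = -caps[j] if rxn.rate_law.form in _REVERSIBLE_FORMS else 0.0
    return StoichiometricModel(
        S=S,
        lower=lower,
        upper=upper,
        reaction_ids=model.reaction_ids,
        species_ids=tuple(s.id for s in internal),
    )


def sample_flux_space(
    smodel: StoichiometricModel,
    n: int,
    seed: int | None = None,
    warmup: int | None = None,
    thin: int | None = None,
) -> pd.DataFrame:
    """Approximately uniform flux samples by hit-and-run.

    The polytope {S v = 0, lb <= v <= ub} is parameterized on the null
    space of S; from an interior point, random directions are drawn and the
    next point is uniform on the feasible chord.  Default warm-up is
    10*dim steps and thinning dim steps.  Every returned sample satisfies
    the constraints to 1e-9.
    """
    N = scipy.linalg.null_space(smodel.S)
    dim = N.shape[1]
    if dim == 0:
        raise ValueError("flux polytope has empty interior (null space is trivial)")
    warmup = 10 * dim if warmup is None else warmup
    thin = dim if thin is None else max(1, thin)
    rng = np.random.default_rng(seed)

    v = _interior_point(smodel)
    tol = 1e-12
    samples = np.empty((n, len(smodel.lower)))
    total = warmup + n * thin
    k = 0
    for it in range(total):
        d = N @ rng.standard_normal(dim)
        nrm = np.linalg.norm(d)
        if nrm < 1e-14:
            continue
        d /= nrm
        # chord extent: lb - v <= t*d <= ub - v componentwise
        with np.errstate(divide="ignore", invalid="ignore"):
            t_up = np.where(d > tol, (smodel.upper - v) / d, np.inf)
            t_dn = np.where(d < -tol, (smodel.lower - v) / d, np.inf)
            t_hi = np.minimum(t_up, t_dn).min()
            t_up2 = np.where(d > tol, (smodel.lower - v) / d, -np.inf)
            t_dn2 = np.where(d < -tol, (smodel.upper - v) / d, -np.inf)
            t_lo = np.maximum(t_up2, t_dn2).max()
        if not np.isfinite(t_hi) or not np.isfinite(t_lo):
            raise ValueError(
                "unbounded direction detected; cap the flux bounds before sampling"
            )
        if t_hi <= t_lo:
            continue
        # sample strictly inside the chord; the move stays exactly on the
        # affine subspace S v = 0 because d lies in the null space
        v = v + rng.uniform(t_lo, t_hi) * d
        if it >= warmup and (it - warmup) % thin == thin - 1 and k < n:
            samples[k] = v
            k += 1
    if k < n:
        raise RuntimeError(f"hit-and-run produced {k}/{n} samples")
    df = pd.DataFrame(samples, columns=list(smodel.reaction_ids))
    return df


def _interior_point(smodel: StoichiometricModel) -> np.ndarray:
    """Chebyshev-style interior point: maximize the margin to the box."""
    n = len(smodel.lower)
    # variables: v (n), margin m (1); maximize m s.t. lb + m <= v <= ub - m
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.zeros((2 * n, n + 1))
    b_ub = np.zeros(2 * n)
    A_ub[:n, :n] = -np.eye(n)
    A_ub[:n, -1] = 1.0
    b_ub[:n] = -smodel.lower
    A_ub[n:, :n] = np.eye(n)
    A_ub[n:, -1] = 1.0
    b_ub[n:] = smodel.upper
    A_eq = np.hstack([smodel.S, np.zeros((smodel.S.shape[0], 1))])
    b_eq = np.zeros(smodel.S.shape[0])
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=[(None, None)] * n + [(0, None)], method="highs",
    )
    if not res.success or res.x[-1] <= 0:
        raise ValueError("flux polytope is empty or has no interior")
    return res.x[:n]


# ---------------------------------------------------------------------------
# Boundaries
# ---------------------------------------------------------------------------

def stoichiometric_boundaries(
    smodel: StoichiometricModel,
    variable_pair: tuple[str, str],
    grid: Sequence[float],
) -> BoundarySet:
    """Envelope of variable 2 at fixed values of variable 1, by LP.

    Variables are reaction ids (their flux).  Infeasible grid points are
    flagged, not raised.
    """
    xi = list(smodel.reaction_ids).index(variable_pair[0])
    yi = list(smodel.reaction_ids).index(variable_pair[1])
    n = len(smodel.lower)
    rows = []
    for x in grid:
        A_eq = np.vstack([smodel.S, np.eye(n)[xi]])
        b_eq = np.concatenate([np.zeros(smodel.S.shape[0]), [x]])
        bounds = list(zip(smodel.lower, smodel.upper))
        c = np.zeros(n)
        c[yi] = 1.0
        lo = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        hi = linprog(-c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        if lo.success and hi.success:
            rows.append((x, lo.x[yi], hi.x[yi], True))
        else:
            rows.append((x, np.nan, np.nan, False))
    table = pd.DataFrame(rows, columns=["x", "y_min", "y_max", "feasible"])
    return BoundarySet(variable_pair=tuple(variable_pair), table=table, source="stoichiometric")


def kinetic_boundaries(
    model: KineticModel,
    variable_pair: tuple[str, str],
    grid: Sequence[float],
    lo: float = 0.1,
    hi: float = 10.0,
    seed: int | None = None,
    swarm_size: int = 20,
    iterations: int = 30,
    pin_tol: float = 0.02,
    glucose_mM: float | None = None,
) -> BoundarySet:
    """Kinetic-side envelope by optimizing enzyme levels.

    For each grid value of variable 1 (a reaction flux), a particle-swarm
    search over log10 enzyme scale factors in [lo, hi]^R maximizes (and
    minimizes) variable 2 subject to variable 1 pinned within ``pin_tol``
    (relative) of the grid value, enforced as a quadratic penalty.  Returned
    envelope points are achieved steady states (feasible by construction);
    when the search fails to pin the grid value the point is flagged
    infeasible.
    """
    from .calibration import particle_swarm  # local import; shared optimizer

    work = model if glucose_mM is None else model.with_boundary("GLC_env", glucose_mM)
    warm = work.steady_state().concentrations
    rid_x, rid_y = variable_pair
    n_r = len(work.reactions)
    ss_seq = np.random.SeedSequence(seed)
    rows = []

    def evaluate(log_factors, sign, x_target, scale_x):
        factors = 10**log_factors
        st = work.steady_state(warm, vmax_scale=factors, eval_budget=15_000)
        if not st.converged:
            return 1e9
        x = st.flux(rid_x)
        y = st.flux(rid_y)
        penalty = ((x - x_target) / scale_x) ** 2
        return sign * y + 100.0 * penalty

    for gi, x_target in enumerate(grid):
        scale_x = max(abs(x_target), 1e-6)
        point = {"x": x_target}
        for key, sign in (("y_max", -1.0), ("y_min", 1.0)):
            seed_i = ss_seq.spawn(1)[0]
            best_x, best_f, _trace = particle_swarm(
                lambda z: evaluate(z, sign, x_target, scale_x),
                lower=np.full(n_r, np.log10(lo)),
                upper=np.full(n_r, np.log10(hi)),
                n_particles=swarm_size,
                iterations=iterations,
                seed=seed_i,
                init=np.zeros((1, n_r)),  # the reference enzyme vector
            )
            st = work.steady_state(warm, vmax_scale=10**best_x, eval_budget=15_000)
            ok = st.converged and abs(st.flux(rid_x) - x_target) <= pin_tol * scale_x + 1e-9
            point[key] = st.flux(rid_y) if st.converged else np.nan
            point.setdefault("feasible", True)
            point["feasible"] = bool(point["feasible"] and ok)
        rows.append((point["x"], point["y_min"], point["y_max"], point["feasible"]))
    table = pd.DataFrame(rows, columns=["x", "y_min", "y_max", "feasible"])
    return BoundarySet(variable_pair=tuple(variable_pair), table=table, source="kinetic")
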
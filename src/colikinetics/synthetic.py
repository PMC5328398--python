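"""Synthetic fixtures: analytic toy networks and pseudo-experimental data.

Everything the test suite needs is generated here, deterministically from a
seed: small kinetic networks whose steady states are known in closed form,
noisy calibration datasets (sigma-weighted Gaussian noise, matching the
weighted least-squares objective), and validation flux tables that emulate
literature compilations of growth/uptake measurements by subsampling a
kinetic ensemble under multiplicative lognormal noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy as sp

from . import ratelaws as rl
from .calibration import CalibrationDataset, DataPoint
from .ensemble import EnsembleResult
from .model import Compartment, KineticModel, Reaction, Species, SteadyState

logger = logging.getLogger(__name__)

__all__ = [
    "make_toy_chain",
    "make_isomerization",
    "make_branch",
    "make_calibration_data",
    "make_validation_table",
]


def _one_compartment() -> list[Compartment]:
    return [Compartment("cyt", 1.0, "cytoplasm")]


def make_toy_chain(
    n_steps: int = 2,
    forms: str = "mass_action",
    feed: float = 1.0,
    rate_constants: tuple[float, ...] | None = None,
    seed: int | None = None,
) -> tuple[KineticModel, SteadyState]:
    """Boundary-fed linear pathway with a closed-form steady state.

    A constant feed v0 produces X1; step i consumes X_i at rate k_i*X_i
    (``mass_action``) or Vmax_i*X_i/(Km_i+X_i) (``saturable``).  At steady
    state every step carries v0, so x_i = v0/k_i (mass action) or
    x_i = Km_i*v0/(Vmax_i-v0) (saturable, requires Vmax_i > v0).
    The returned analytic state satisfies the model's own residual check.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if forms not in ("mass_action", "saturable"):
        raise ValueError(f"unsupported form '{forms}'")
    rng = np.random.default_rng(seed)
    if rate_constants is None:
        rate_constants = tuple(float(k) for k in rng.uniform(0.5, 3.0, n_steps))
    if len(rate_constants) != n_steps:
        raise ValueError("need one rate constant per step")
    if any(k <= 0 for k in rate_constants):
        raise ValueError(
            "zero-capacity step: no steady state with positive throughput"
        )

    species = []
    reactions = [
        Reaction("FEED", {"X1": 1.0}, rl.constant_flux_law(feed), "cyt")
    ]
    conc = {}
    kms = {}
    for i, k in enumerate(rate_constants, start=1):
        sid = f"X{i}"
        if forms == "mass_action":
            x_ss = feed / k
            law = rl.first_order_law(sid, k)
        else:
            vmax = max(k, 2.0 * feed)  # ensure capacity above throughput
            km = 1.0
            x_ss = km * feed / (vmax - feed)
            law = rl.irreversible_mm_law({sid: km}, vmax)
            kms[sid] = km
        conc[sid] = x_ss
        stoich = {sid: -1.0}
        if i < n_steps:
            stoich[f"X{i+1}"] = 1.0
        reactions.append(Reaction(f"R{i}", stoich, law, "cyt"))
        species.append(Species(sid, "cyt", x_ss))
    model = KineticModel(_one_compartment(), species, reactions, name="toy_chain")
    x = model.initial_concentrations
    v = model.evaluate_rates(x)
    resid = float(np.max(np.abs(model.rhs(x))))
    state = SteadyState(
        concentrations=x,
        fluxes=v,
        residual_norm=resid,
        converged=resid <= 1e-10,
        species_ids=model.species_ids,
        reaction_ids=model.reaction_ids,
    )
    if not state.converged:
        raise RuntimeError("analytic toy steady state failed its residual check")
    return model, state


def make_isomerization(
    kf: float = 1.0, kr: float = 0.5, a0: float = 1.0, b0: float = 0.0
) -> KineticModel:
    """Closed reversible isomerization A <-> B (mass action).

    The relaxation is a single exponential with rate kf + kr towards
    A_eq = (a0+b0) * kr/(kf+kr); the total A+B is conserved.
    """
    species = [Species("A", "cyt", a0), Species("B", "cyt", b0)]
    law = rl.mass_action_reversible_law(["A"], ["B"], kf, kf / kr)
    reactions = [Reaction("ISO", {"A": -1.0, "B": 1.0}, law, "cyt")]
    return KineticModel(_one_compartment(), species, reactions, name="isomerization")


def make_branch(
    feed: float = 1.0, k1: float = 1.0, k2: float = 2.0, seed: int | None = None
) -> tuple[KineticModel, SteadyState]:
    """Branch point: feed -> X, X -> (two first-order branches).

    Steady state: x = feed/(k1+k2); branch fluxes split in proportion to
    the rate constants.
    """
    species = [Species("X", "cyt", feed / (k1 + k2))]
    reactions = [
        Reaction("FEED", {"X": 1.0}, rl.constant_flux_law(feed), "cyt"),
        Reaction("B1", {"X": -1.0}, rl.first_order_law("X", k1), "cyt"),
        Reaction("B2", {"X": -1.0}, rl.first_order_law("X", k2), "cyt"),
    ]
    model = KineticModel(_one_compartment(), species, reactions, name="toy_branch")
    x = model.initial_concentrations
    v = model.evaluate_rates(x)
    state = SteadyState(
        concentrations=x, fluxes=v,
        residual_norm=float(np.max(np.abs(model.rhs(x)))),
        converged=True,
        species_ids=model.species_ids, reaction_ids=model.reaction_ids,
    )
    return model, state


def make_calibration_data(
    model: KineticModel,
    observables: list[tuple[str, str]] | None = None,
    times: list[float] | None = None,
    noise_sigma: float = 0.05,
    seed: int | None = None,
) -> CalibrationDataset:
    """Noisy pseudo-experimental dataset from a solvable model.

    Steady-state fluxes/concentrations (and optional time-course
    concentrations at ``times``) are simulated, then perturbed with Gaussian
    noise of relative standard deviation ``noise_sigma``; each point records
    its sigma, so the weighted objective at the true parameters follows a
    chi-squared distribution.
    """
    rng = np.random.default_rng(seed)
    ss = model.steady_state()
    if not ss.converged:
        raise RuntimeError("model has no steady state under the reference condition")
    if observables is None:
        observables = [(rid, "flux") for rid in model.reaction_ids] + [
            (s.id, "concentration") for s in model.species if not s.is_boundary
        ]
    # with zero noise the weights still need a scale: use a nominal 5%
    weight_sigma = noise_sigma if noise_sigma > 0 else 0.05
    points = []
    for obs, kind in observables:
        y = ss.flux(obs) if kind == "flux" else ss.concentration(obs)
        sigma = max(abs(y) * weight_sigma, 1e-9)
        value = y + rng.normal(0.0, noise_sigma * abs(y)) if noise_sigma > 0 else y
        points.append(DataPoint(observable=obs, kind=kind, value=value, sigma=sigma))
    if times:
        traj = model.simulate(np.concatenate([[0.0], np.asarray(times, float)]))
        for sid in (s.id for s in model.species if not s.is_boundary):
            for t in times:
                ti = int(np.argmin(np.abs(traj.t - t)))
                y = float(traj.series(sid)[ti])
                sigma = max(abs(y) * weight_sigma, 1e-9)
                value = y + rng.normal(0.0, noise_sigma * abs(y)) if noise_sigma > 0 else y
                points.append(
                    DataPoint(observable=sid, kind="concentration",
                              value=value, sigma=sigma, time=t)
                )
    return CalibrationDataset(points)


def make_validation_table(
    ensemble: EnsembleResult,
    n_rows: int = 254,
    noise_sigma: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic validation flux table emulating a literature compilation.

    Rows are converged ensemble states subsampled without replacement, with
    multiplicative lognormal noise (flux measurements are scale-family) on
    growth rate, glucose uptake, oxygen uptake and citrate-synthase flux.
    """
    states = ensemble.converged_states()
    if len(states) < n_rows:
        raise ValueError(
            f"ensemble has {len(states)} converged states, need {n_rows}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(states), size=n_rows, replace=False)
    rows = []
    for i, si in enumerate(idx):
        st = states[si]
        noise = rng.lognormal(0.0, noise_sigma, size=4) if noise_sigma > 0 else np.ones(4)
        rows.append(
            {
                "experiment": f"synthetic_{i:04d}",
                "growth_rate": st.flux("GROWTH") * 3600.0 * noise[0],
                "glucose_uptake": st.flux("PTS") * noise[1],
                "o2_uptake": st.flux("CYTBO") * noise[2],
                "citrate_synthase_flux": st.flux("GLT") * noise[3],
            }
        )
    return pd.DataFrame(rows)
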
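"""Metabolic control analysis (MCA).

Scaled flux and concentration control coefficients

    C^J_E = d ln J / d ln E        C^M_E = d ln M / d ln E

quantify the fractional change of every steady-state flux J and metabolite
concentration M per fractional change in the capacity (Vmax) of step E.
They are computed by central finite differences in log space: each step's
Vmax is perturbed up and down by a small relative factor and the steady
state re-solved.  The summation theorems (flux rows sum to 1, concentration
rows to 0) double as a step-size validation.

The overall control of a step is the L2 norm of its column of control
coefficients, one number per step for fluxes and one for concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import KineticModel, SteadyState

logger = logging.getLogger(__name__)

__all__ = [
    "ControlMatrices",
    "OverallControl",
    "control_coefficients",
    "overall_control",
    "control_summary",
    "control_robustness",
]

#: Default relative finite-difference step on ln Vmax.
DEFAULT_STEP = 1e-3

#: Reference fluxes smaller than this (mM/s) are excluded from scaled flux
#: control coefficients (d ln J undefined at J ~ 0).
ZERO_FLUX_TOL = 1e-12


@dataclass
class ControlMatrices:
    """Scaled control coefficients at a reference steady state.

    ``C_J``: DataFrame [flux x step]; ``C_M``: DataFrame [metabolite x step].
    Rows with (near-)zero reference flux or concentration are excluded and
    listed in ``excluded_fluxes`` / ``excluded_metabolites``; steps whose
    perturbed steady states failed to converge are in ``failed_steps``.
    """

    C_J: pd.DataFrame
    C_M: pd.DataFrame
    reference: SteadyState
    excluded_fluxes: tuple[str, ...] = ()
    excluded_metabolites: tuple[str, ...] = ()
    failed_steps: tuple[str, ...] = ()


@dataclass
class OverallControl:
    """Per-step L2 norms of flux (CJ) and concentration (CC) control."""

    CJ: pd.Series
    CC: pd.Series


def control_coefficients(
    model: KineticModel,
    reference: SteadyState | None = None,
    perturbation: float = DEFAULT_STEP,
    steps: list[str] | None = None,
) -> ControlMatrices:
    """Scaled flux/concentration control coefficients by central differences.

    The steady state is re-solved at Vmax*exp(+/-h) for every step E (warm
    started from the reference); coefficients are
    (ln q(+h) - ln q(-h)) / (2h).  A step whose perturbed states fail to
    converge is retried with halved h, then marked failed (NaN column).
    """
    if reference is None:
        reference = model.steady_state()
    if not reference.converged:
        raise ValueError("reference steady state did not converge")
    rids = list(model.reaction_ids)
    sids = [s.id for s in model.species if not s.is_boundary]
    steps = rids if steps is None else list(steps)

    flux_ref = pd.Series(reference.fluxes, index=rids)
    keep_flux = flux_ref.abs() > ZERO_FLUX_TOL
    conc_ref = pd.Series(
        [reference.concentration(s) for s in sids], index=sids
    )
    keep_conc = conc_ref > ZERO_FLUX_TOL

    CJ = pd.DataFrame(index=flux_ref.index[keep_flux], columns=steps, dtype=float)
    CM = pd.DataFrame(index=conc_ref.index[keep_conc], columns=steps, dtype=float)
    failed = []
    warm = reference.concentrations
    for rid in steps:
        h = perturbation
        for attempt in range(2):
            up = _solve_scaled(model, rid, np.exp(h), warm)
            dn = _solve_scaled(model, rid, np.exp(-h), warm)
            if up is not None and dn is not None:
                lj = (
                    np.log(np.abs(up.fluxes)) - np.log(np.abs(dn.fluxes))
                ) / (2 * h)
                CJ[rid] = pd.Series(lj, index=rids)[keep_flux.index[keep_flux]]
                cu = np.array([up.concentration(s) for s in sids])
                cd = np.array([dn.concentration(s) for s in sids])
                lm = (np.log(cu) - np.log(cd)) / (2 * h)
                CM[rid] = pd.Series(lm, index=sids)[keep_conc.index[keep_conc]]
                break
            h /= 2
        else:
            failed.append(rid)
            CJ[rid] = np.nan
            CM[rid] = np.nan
    if failed:
        logger.warning("control analysis: %d steps failed: %s", len(failed), failed)
    return ControlMatrices(
        C_J=CJ,
        C_M=CM,
        reference=reference,
        excluded_fluxes=tuple(flux_ref.index[~keep_flux]),
        excluded_metabolites=tuple(conc_ref.index[~keep_conc]),
        failed_steps=tuple(failed),
    )


def _solve_scaled(model, rid, factor, warm):
    ss = model.steady_state(warm, vmax_scale={rid: factor}, eval_budget=20_000)
    if not ss.converged:
        return None
    return ss


def overall_control(matrices: ControlMatrices) -> OverallControl:
    """L2 norm of each step's control coefficients (fluxes, concentrations)."""
    cj = np.sqrt((matrices.C_J**2).sum(axis=0, skipna=False))
    cc = np.sqrt((matrices.C_M**2).sum(axis=0, skipna=False))
    return OverallControl(CJ=cj, CC=cc)


def control_summary(
    overall: OverallControl,
    matrices: ControlMatrices,
    environment_steps: tuple[str, ...] = ("GLC_FEED",),
    band: float = 0.3,
) -> dict:
    """Headline statistics of the control distribution.

    Splits steps into the environment (glucose supply) and enzymes, and
    reports the fraction of enzyme coefficients inside [-band, band], the
    fraction of environment coefficients above band, and the Pearson
    correlation between per-step overall flux and concentration control.
    """
    env = [s for s in matrices.C_J.columns if s in environment_steps]
    enz = [s for s in matrices.C_J.columns if s not in environment_steps]
    if len(matrices.C_J.columns) < 3:
        raise ValueError("correlation undefined with fewer than 3 steps")

    def _frac_within(df, cols):
        vals = df[cols].to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        return float(np.mean(np.abs(vals) <= band)) if vals.size else np.nan

    def _frac_above(df, cols):
        vals = df[cols].to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals > band)) if vals.size else np.nan

    cj, cc = overall.CJ, overall.CC
    mask = np.isfinite(cj.to_numpy()) & np.isfinite(cc.to_numpy())
    r, p = stats.pearsonr(cj[mask], cc[mask])
    return {
        "flux_enzyme_fraction_within_band": _frac_within(matrices.C_J, enz),
        "flux_environment_fraction_above_band": _frac_above(matrices.C_J, env),
        "conc_enzyme_fraction_within_band": _frac_within(matrices.C_M, enz),
        "conc_environment_fraction_above_band": _frac_above(matrices.C_M, env),
        "pearson_overall_flux_vs_conc": float(r),
        "pearson_pvalue": float(p),
        "band": band,
    }


def control_robustness(
    model: KineticModel,
    n_samples: int,
    spread: float = 0.2,
    seed: int | None = None,
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> dict:
    """Distribution of overall controls under parameter uncertainty.

    Every kinetic parameter is independently resampled uniformly within
    ``+/-spread`` of its reference value, the steady state and overall
    controls recomputed.  Per-sample substreams are spawned from the master
    seed, so the result is reproducible regardless of evaluation order.
    Non-converged samples are dropped and counted; more than 50% failures
    aborts.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_samples)
    p0 = model.parameter_vector
    cj_rows, cc_rows = [], []
    failures = 0
    warm = model.steady_state().concentrations
    for child in children:
        rng = np.random.default_rng(child)
        p = p0 * rng.uniform(1 - spread, 1 + spread, size=p0.shape)
        ref = model.steady_state(warm, parameters=p, eval_budget=20_000)
        if not ref.converged:
            failures += 1
            continue
        mats = _control_with_params(model, p, ref)
        oc = overall_control(mats)
        cj_rows.append(oc.CJ)
        cc_rows.append(oc.CC)
    if failures > n_samples / 2:
        raise RuntimeError(
            f"robustness analysis: {failures}/{n_samples} samples failed to converge"
        )
    cj = pd.DataFrame(cj_rows)
    cc = pd.DataFrame(cc_rows)
    return {
        "CJ_quantiles": cj.quantile(list(quantiles)),
        "CC_quantiles": cc.quantile(list(quantiles)),
        "n_converged": len(cj_rows),
        "n_failed": failures,
    }


def _control_with_params(model, p, ref):
    """Control coefficients at a non-reference parameter vector."""
    rids = list(model.reaction_ids)
    sids = [s.id for s in model.species if not s.is_boundary]
    h = DEFAULT_STEP
    flux_ref = pd.Series(ref.fluxes, index=rids)
    keep_flux = flux_ref.abs() > ZERO_FLUX_TOL
    conc_ref = pd.Series([ref.concentration(s) for s in sids], index=sids)
    keep_conc = conc_ref > ZERO_FLUX_TOL
    CJ = pd.DataFrame(index=flux_ref.index[keep_flux], columns=rids, dtype=float)
    CM = pd.DataFrame(index=conc_ref.index[keep_conc], columns=rids, dtype=float)
    warm = ref.concentrations
    for rid in rids:
        up = model.steady_state(warm, parameters=p, vmax_scale={rid: np.exp(h)}, eval_budget=20_000)
        dn = model.steady_state(warm, parameters=p, vmax_scale={rid: np.exp(-h)}, eval_budget=20_000)
        if not (up.converged and dn.converged):
            CJ[rid] = np.nan
            CM[rid] = np.nan
            continue
        lj = (np.log(np.abs(up.fluxes)) - np.log(np.abs(dn.fluxes))) / (2 * h)
        CJ[rid] = pd.Series(lj, index=rids)[keep_flux.index[keep_flux]]
        cu = np.array([up.concentration(s) for s in sids])
        cd = np.array([dn.concentration(s) for s in sids])
        CM[rid] = pd.Series((np.log(cu) - np.log(cd)) / (2 * h), index=sids)[
            keep_conc.index[keep_conc]
        ]
    return ControlMatrices(C_J=CJ, C_M=CM, reference=ref)
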
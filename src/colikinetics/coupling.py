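"""Functional-coupling statistics over ensembles of steady states.

For every converged steady state of a random-enzyme ensemble a set of
systemic physiological variables is computed (growth rate, uptake rates,
cofactor production rates and yields, sum of fluxes, enzyme cost, total
metabolite pool, and representative pathway fluxes).  Pairwise couplings
between the variables are then quantified with Spearman rank correlation
and with plug-in mutual information on equal-frequency-binned data; a
coupling that is monotonic shows up in both, a non-monotonic one only in
the mutual information.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .ensemble import EnsembleResult
from .model import KineticModel

logger = logging.getLogger(__name__)

__all__ = [
    "systemic_variables",
    "enzyme_cost",
    "load_enzyme_table",
    "spearman_matrix",
    "mutual_information_matrix",
    "homeostasis_summary",
    "DEFAULT_ENZYME_UM",
]

#: Default enzyme concentration when no measurement is tabulated (uM).
DEFAULT_ENZYME_UM = 18.0

#: Cofactors whose gross production rates are tabulated.
_COFACTORS = ("ATP", "NADH", "NADPH")

#: Representative pathway reactions (absolute and uptake-relative fluxes).
_PATHWAY_REPS = {
    "glycolysis": "PFK",
    "ppp": "ZWF",
    "tca": "GLT",  # citrate synthase
    "acetate_overflow": "ACK",
    "oxphos": "CYTBO",
}

#: Environment/exchange reactions excluded from the sum of fluxes.
_EXCHANGE_PREFIXES = ("GLC_FEED", "ACE_OUT", "XCH_")


def load_enzyme_table(path: str | None = None) -> pd.DataFrame:
    """Enzyme concentration/size table: columns reaction, conc_uM, aa_count.

    Without a path, the table packaged for the reduced reference model is
    used (synthetic values; see the file header).
    """
    if path is None:
        ref = resources.files("colikinetics").joinpath("data/enzyme_costs.tsv")
        with resources.as_file(ref) as f:
            return pd.read_csv(f, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def enzyme_cost(
    enzyme_scale_factors: Mapping[str, float] | np.ndarray,
    enzyme_concentrations: Mapping[str, float],
    aa_counts: Mapping[str, float],
    reaction_ids: tuple[str, ...] | None = None,
) -> float:
    """Proteome-investment proxy: sum of factor * concentration * length.

    Units: residue-uM.  Reactions without a tabulated concentration use the
    average enzyme concentration (18 uM).  Negative scale factors are
    rejected.
    """
    if not isinstance(enzyme_scale_factors, Mapping):
        if reaction_ids is None:
            raise ValueError("reaction_ids required with an array of factors")
        enzyme_scale_factors = dict(zip(reaction_ids, enzyme_scale_factors))
    total = 0.0
    for rid, factor in enzyme_scale_factors.items():
        if factor < 0:
            raise ValueError(f"negative enzyme scale factor for '{rid}'")
        conc = enzyme_concentrations.get(rid, DEFAULT_ENZYME_UM)
        aa = aa_counts.get(rid)
        if aa is None:
            continue  # reaction without an enzyme (e.g. feed, leak)
        total += factor * conc * aa
    return float(total)


def systemic_variables(
    ensemble: EnsembleResult,
    model: KineticModel | None = None,
    enzyme_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-steady-state physiological summary table (converged states only).

    Units: growth rate 1/h; uptake/production rates mM/s (cytoplasm
    referenced, gross stoichiometry-weighted production for cofactors);
    yields are rates per glucose uptake; sum of fluxes is the sum of
    absolute intracellular amount fluxes; enzyme cost in residue-uM; total
    pool in mM (cytoplasmic species).  Rows with zero glucose uptake have
    undefined yields (NaN) and are excluded from rank statistics downstream.
    """
    model = ensemble.model if model is None else model
    if enzyme_table is None:
        enzyme_table = load_enzyme_table()
    conc_map = dict(zip(enzyme_table["reaction"], enzyme_table["conc_uM"]))
    aa_map = dict(zip(enzyme_table["reaction"], enzyme_table["aa_count"]))

    rids = list(model.reaction_ids)
    c = model.compiled
    rvol = c.reaction_volumes
    S = c.S
    sidx = {s: i for i, s in enumerate(model.species_ids)}
    cyt_idx = [
        i for i, sp in enumerate(model.species)
        if sp.compartment == "cyt" and not sp.is_boundary
    ]
    internal = np.array([not r.id.startswith(_EXCHANGE_PREFIXES) for r in model.reactions])
    vcyt = model.compartment("cyt").volume

    rows = []
    for sample, state in zip(ensemble.converged_samples(), ensemble.converged_states()):
        amount_flux = state.fluxes * rvol  # amount units
        uptake = state.flux("PTS")
        growth = state.flux("GROWTH") * 3600.0
        o2 = state.flux("CYTBO")
        row = {
            "growth_rate": growth,
            "glucose_uptake": uptake,
            "o2_uptake": o2,
        }
        for cof in _COFACTORS:
            contrib = S[sidx[cof], :] * amount_flux
            row[f"{cof.lower()}_production"] = float(np.sum(contrib[contrib > 0])) / vcyt
        sum_flux = float(np.sum(np.abs(amount_flux[internal]))) / vcyt
        row["sum_fluxes"] = sum_flux
        row["enzyme_cost"] = enzyme_cost(
            dict(zip(rids, sample.factors)), conc_map, aa_map
        )
        row["total_pool"] = float(np.sum(state.concentrations[cyt_idx]))
        if uptake > 0:
            row["biomass_yield"] = growth / uptake
            for cof in _COFACTORS:
                row[f"{cof.lower()}_yield"] = row[f"{cof.lower()}_production"] / uptake
            row["sum_fluxes_per_glucose"] = sum_flux / uptake
        else:
            row["biomass_yield"] = np.nan
            for cof in _COFACTORS:
                row[f"{cof.lower()}_yield"] = np.nan
            row["sum_fluxes_per_glucose"] = np.nan
        row["atp_per_sum_fluxes"] = (
            row["atp_production"] / sum_flux if sum_flux > 0 else np.nan
        )
        row["enzyme_cost_per_sum_fluxes"] = (
            row["enzyme_cost"] / sum_flux if sum_flux > 0 else np.nan
        )
        row["growth_per_sum_fluxes"] = growth / sum_flux if sum_flux > 0 else np.nan
        for pw, rid in _PATHWAY_REPS.items():
            v = state.flux(rid)
            row[f"flux_{pw}"] = v
            row[f"relflux_{pw}"] = v / uptake if uptake > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average ranks on ties).

    Requires at least 10 rows.  Pairs involving a constant column are
    undefined and reported as NaN.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 states for rank statistics")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = table.corr(method="spearman")
    return rho


def _equal_frequency_bins(x: pd.Series, n_bins: int) -> np.ndarray:
    codes, _ = pd.factorize(pd.qcut(x.rank(method="average"), n_bins, duplicates="drop"))
    return codes


def mutual_information_matrix(
    table: pd.DataFrame, n_bins: int | None = None
) -> pd.DataFrame:
    """Plug-in discrete mutual information on equal-frequency bins (nats).

    Default bin count is floor(n^(1/3)) capped at 30 (>= 2).  The diagonal
    is the empirical marginal entropy of the binned column.  Constant
    columns carry no information; their rows are zero (with a warning).
    """
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 states for mutual information")
    if n_bins is None:
        n_bins = int(np.clip(np.floor(n ** (1 / 3)), 2, 30))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cols = list(table.columns)
    codes = {}
    for col in cols:
        x = table[col].dropna()
        if x.nunique() <= 1:
            warnings.warn(f"column '{col}' is constant; MI set to 0")
            codes[col] = None
        else:
            codes[col] = (_equal_frequency_bins(x, n_bins), x.index)
    mi = pd.DataFrame(0.0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if codes[a] is None or codes[b] is None:
                val = 0.0
            else:
                ca, ia = codes[a]
                cb, ib = codes[b]
                common = ia.intersection(ib)
                xa = pd.Series(ca, index=ia).loc[common]
                xb = pd.Series(cb, index=ib).loc[common]
                val = float(mutual_info_score(xa, xb))
            mi.loc[a, b] = mi.loc[b, a] = val
    mi.attrs["n_bins"] = n_bins
    mi.attrs["units"] = "nats"
    mi.attrs["binning"] = "equal_frequency"
    return mi


def homeostasis_summary(
    totals: np.ndarray | pd.Series,
    reference_total_mM: float,
    k: float = 3.0,
    n_hist_bins: int = 30,
) -> dict:
    """Distribution of the total intracellular metabolite pool.

    Returns the histogram of per-state totals (log10 scale), the cumulative
    frequency curve, and the fraction of states whose total pool stays
    within [ref/k, ref*k] of the calibrated reference total.
    """
    totals = np.asarray(totals, float)
    totals = totals[np.isfinite(totals)]
    if totals.size == 0:
        raise ValueError("no states supplied")
    logt = np.log10(totals)
    hist, edges = np.histogram(logt, bins=n_hist_bins)
    order = np.sort(totals)
    cumfreq = np.arange(1, totals.size + 1) / totals.size
    within = np.mean((totals >= reference_total_mM / k) & (totals <= reference_total_mM * k))
    return {
        "totals_mM": totals,
        "hist_counts": hist,
        "hist_edges_log10": edges,
        "cumulative_x_mM": order,
        "cumulative_freq": cumfreq,
        "fraction_within_k_fold": float(within),
        "k": k,
        "reference_total_mM": reference_total_mM,
    }
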
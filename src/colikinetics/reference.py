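"""The packaged reference model: a reduced kinetic model of *E. coli*
central carbon and energy metabolism.

The model is synthetic: it is authored here, not transcribed from a
published parameter set, but it follows the architecture of the full-scale
kinetic models of *E. coli* central metabolism (e.g. BioModels entry
MODEL1505110000, which :func:`colikinetics.io.read_model_sbml` can load if
the file is supplied):

* three compartments — environment, periplasm (20% of cell volume) and
  cytoplasm — with chemostat feed (GLC_FEED) and washout (ACE_OUT)
  reactions on the environment;
* porin-facilitated exchange of glucose and acetate across the outer
  membrane (reversible Michaelis-Menten);
* PEP-dependent glucose uptake (PTS), glycolysis, an oxidative/lumped
  non-oxidative pentose-phosphate branch, anaplerosis, the TCA cycle and
  acetate overflow;
* a detailed oxidative-phosphorylation chain (NDH-I, NDH-II, SQR,
  cytochrome *bo* oxidase, ATP synthase) with proton pumping
  (2 H+/e- pumps, 4 H+/ATP) and the trans-membrane pH difference
  attenuating the pumps and driving the synthase;
* nucleotide interconversion (ADK, CYA, DOS, ATP_NGAM) and
  transhydrogenase (PNT);
* a single growth reaction consuming all biomass precursors in fixed
  stoichiometric proportions with a multiplicative-saturation rate law.

Calibration is by construction: reference concentrations and a
stoichiometrically balanced reference flux distribution are fixed first
(chemostat at dilution rate 0.1 1/h), then every Vmax is solved so that the
reference state is an exact steady state of the rate laws.  Long-range
regulatory interactions (modifier-only edges): PEP inhibition of PFK, FBP
activation of PYK, acetyl-CoA activation of PPC, and NADH inhibition of
citrate synthase.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from . import ratelaws as rl
from .model import Compartment, KineticModel, Reaction, Species

__all__ = [
    "build_reference_model",
    "excess_glucose_model",
    "REFERENCE_GROWTH_RATE",
    "REFERENCE_CONCENTRATIONS",
    "EXCESS_GLUCOSE_MM",
]

#: Reference specific growth rate, 0.1 1/h in 1/s (chemostat dilution rate).
REFERENCE_GROWTH_RATE = 0.1 / 3600.0

#: Extracellular glucose concentration of the excess-glucose condition (mM).
EXCESS_GLUCOSE_MM = 10.0

_V_ENV, _V_PER, _V_CYT = 1.0, 0.2, 0.8  # periplasm = 20% of cell volume

#: Reference (calibrated) concentrations, mM.
REFERENCE_CONCENTRATIONS: dict[str, float] = {
    "GLC_env": 0.05, "ACE_env": 0.4,
    "GLC_per": 0.02, "ACE_per": 0.6, "H_per": 10 ** -3.5,
    "G6P": 1.0, "F6P": 0.3, "FBP": 1.5, "GAP": 0.1, "PEP": 1.8, "PYR": 0.4,
    "AcCoA": 0.3, "CoA": 0.5, "P5P": 0.8, "CIT": 1.5, "KG": 0.5, "SUC": 0.8,
    "FUM": 0.3, "OAA": 0.05, "ATP": 2.5, "ADP": 0.6, "AMP": 0.3,
    "cAMP": 0.3, "P": 10.0, "NAD": 1.5, "NADH": 0.1, "NADP": 0.1,
    "NADPH": 0.15, "FAD": 0.2, "FADH2": 0.05, "Q": 0.6, "QH2": 0.4,
    "O2": 0.21, "H_cyt": 1e-4,
    "P_env": 64.0,  # M9-medium phosphate reservoir
}

#: Biomass stoichiometry: precursor demand (mM consumed per unit of the
#: growth rate, i.e. per 1/s of specific growth, cytoplasm-referenced).
_BIOMASS = {
    "G6P": 200.0, "P5P": 300.0, "PEP": 150.0, "PYR": 300.0, "AcCoA": 300.0,
    "OAA": 200.0, "KG": 300.0, "NADPH": 1200.0, "ATP": 6000.0,
}

# Pinned reference fluxes (amount units, mM*volume/s); the remaining fluxes
# follow from species balances in _reference_fluxes().
_PIN = {
    "PTS": 0.04,      # glucose uptake
    "ZWF": 0.008,     # oxidative PPP branch
    "ACK": 0.004,     # acetate overflow
    "NDHI": 0.10,     # proton-pumping NADH dehydrogenase share
    "CYA": 2e-4,      # cAMP turnover
    "H_LEAK": 0.04,   # passive proton leak across the inner membrane
    "GS": 5e-4,       # glyoxylate shunt (lumped isocitrate lyase + malate synthase)
    "PPS": 2e-4,      # PEP synthetase (gluconeogenic PEP supply)
    # overflow/spill valves: engaged at roughly ten-fold pool overshoot
    # (reference flux ~0.01% of the carrying pathway)
    "G6P_SPILL": 4e-6,
    "P5P_SPILL": 8e-7,
    "MGS": 5.7e-6,
    "FBP_SPILL": 3e-6,
    "PEP_SPILL": 5.7e-6,
    "PYR_OUT": 3.5e-6,
    "CIT_OUT": 2.4e-6,
    "KG_OUT": 1.8e-6,
    "SUC_OUT": 1.8e-6,
    "PPK": 4e-5,
}


def _reference_fluxes(model: KineticModel) -> dict[str, float]:
    """Stoichiometrically balanced reference flux distribution (amounts/s).

    A handful of fluxes that set the physiology are pinned (glucose uptake,
    PPP split, acetate overflow, NDH-I share, proton leak, valve fluxes,
    growth at the chemostat dilution rate); the remaining fluxes are the
    unique solution of the species balances S_dyn @ F = 0.
    """
    g = REFERENCE_GROWTH_RATE * _V_CYT
    pinned = dict(_PIN)
    pinned["GROWTH"] = g

    rids = list(model.reaction_ids)
    c = model.compiled
    A = c.S[c.dynamic, :]
    free = [j for j, rid in enumerate(rids) if rid not in pinned]
    fixed = [j for j, rid in enumerate(rids) if rid in pinned]
    fp = np.array([pinned[rids[j]] for j in fixed])
    b = -A[:, fixed] @ fp
    sol, *_ = np.linalg.lstsq(A[:, free], b, rcond=None)
    resid = A[:, free] @ sol - b
    if np.max(np.abs(resid)) > 1e-12:
        raise RuntimeError("pinned fluxes are inconsistent with the stoichiometry")
    F = dict(pinned)
    F.update({rids[j]: float(v) for j, v in zip(free, sol)})
    return F


def _species() -> list[Species]:
    c = REFERENCE_CONCENTRATIONS
    env = ["GLC_env", "ACE_env", "P_env"]
    per = ["GLC_per", "ACE_per", "H_per"]
    cyt = [
        "G6P", "F6P", "FBP", "GAP", "PEP", "PYR", "AcCoA", "CoA", "P5P",
        "CIT", "KG", "SUC", "FUM", "OAA", "ATP", "ADP", "AMP", "cAMP", "P",
        "NAD", "NADH", "NADP", "NADPH", "FAD", "FADH2", "Q", "QH2",
        "O2", "H_cyt",
    ]
    boundary = {"O2", "H_cyt", "P_env"}
    out = []
    for comp, ids in (("env", env), ("per", per), ("cyt", cyt)):
        for sid in ids:
            out.append(
                Species(sid, comp, c[sid], is_boundary=sid in boundary)
            )
    return out


def _dph_expr() -> sp.Expr:
    return rl.delta_ph_expr(sp.Symbol("H_cyt"), sp.Symbol("H_per"))


def _gamma(substrates: dict[str, tuple[float, float]],
           products: dict[str, tuple[float, float]]) -> float:
    """Reaction quotient at the reference concentrations."""
    g = 1.0
    for sid, (m, _km) in products.items():
        g *= REFERENCE_CONCENTRATIONS[sid] ** m
    for sid, (n, _km) in substrates.items():
        g /= REFERENCE_CONCENTRATIONS[sid] ** n
    return g


def _enzyme(sub: dict[str, tuple[float, float]],
            prod: dict[str, tuple[float, float]],
            displacement: float, **mods) -> rl.RateLaw:
    """Convenience-kinetics law with Keq set ``displacement``-fold beyond the
    reference reaction quotient (so the reference state runs forward at the
    stated thermodynamic displacement)."""
    return rl.convenience_law(sub, prod, 1.0,
                              displacement * _gamma(sub, prod), **mods)


def _reactions() -> list[Reaction]:
    """Reaction list with unit Vmax; calibration rescales Vmax afterwards."""
    quinone = {"NADH": "NADH", "NAD": "NAD", "Q": "Q", "QH2": "QH2"}

    def porin(sub: str, prod: str, km: float) -> rl.RateLaw:
        s, p = sp.Symbol(sub), sp.Symbol(prod)
        vm, k, keq = sp.Symbol("Vmax"), sp.Symbol("Km"), sp.Symbol("Keq")
        expr = vm * (s - p / keq) / (k + s + p / keq)
        return rl.RateLaw("reversible_michaelis_menten", expr,
                          {"Vmax": 1.0, "Km": km, "Keq": 1.0})

    R = Reaction
    return [
        # environment & exchange
        R("GLC_FEED", {"GLC_env": 1}, rl.constant_flux_law(1.0), "env"),
        R("XCH_GLC", {"GLC_env": -1, "GLC_per": 1}, porin("GLC_env", "GLC_per", 0.5), "per"),
        R("XCH_ACE", {"ACE_per": -1, "ACE_env": 1}, porin("ACE_per", "ACE_env", 1.0), "per"),
        R("ACE_OUT", {"ACE_env": -1}, rl.first_order_law("ACE_env", 1.0), "env"),
        R("XCH_P", {"P_env": -1, "P": 1}, porin("P_env", "P", 10.0), "cyt"),
        # glucose uptake and glycolysis
        R("PTS", {"GLC_per": -1, "PEP": -1, "G6P": 1, "PYR": 1},
          _enzyme({"GLC_per": (1, 0.02), "PEP": (1, 1.0)},
                  {"G6P": (1, 1.0), "PYR": (1, 0.4)}, 100.0), "cyt"),
        R("PGI", {"G6P": -1, "F6P": 1},
          _enzyme({"G6P": (1, 1.0)}, {"F6P": (1, 0.3)}, 1.2), "cyt"),
        R("PFK", {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1},
          _enzyme({"F6P": (1, 0.3), "ATP": (1, 0.3)},
                  {"FBP": (1, 1.5), "ADP": (1, 0.6)}, 100.0,
                  inhibitors={"PEP": 2.0}), "cyt", modifiers=("PEP",)),
        R("FBA", {"FBP": -1, "GAP": 2},
          _enzyme({"FBP": (1, 1.5)}, {"GAP": (2, 0.1)}, 5.0), "cyt"),
        R("GDH", {"GAP": -1, "NAD": -1, "ADP": -1, "P": -1, "PEP": 1, "NADH": 1, "ATP": 1},
          _enzyme({"GAP": (1, 0.3), "NAD": (1, 0.5), "ADP": (1, 0.3), "P": (1, 5.0)},
                  {"PEP": (1, 1.8), "NADH": (1, 0.1), "ATP": (1, 2.5)}, 5.0), "cyt"),
        R("PYK", {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1},
          _enzyme({"PEP": (1, 1.5), "ADP": (1, 0.3)},
                  {"PYR": (1, 0.4), "ATP": (1, 2.5)}, 100.0,
                  activators={"FBP": 0.5}), "cyt", modifiers=("FBP",)),
        R("PPS", {"PYR": -1, "ATP": -1, "PEP": 1, "AMP": 1, "P": 1},
          _enzyme({"PYR": (1, 0.4), "ATP": (1, 2.5)},
                  {"PEP": (1, 1.8), "AMP": (1, 0.3), "P": (1, 10.0)}, 100.0), "cyt"),
        # pentose-phosphate branch
        R("ZWF", {"G6P": -1, "NADP": -2, "P5P": 1, "NADPH": 2},
          _enzyme({"G6P": (1, 0.5), "NADP": (2, 0.05)},
                  {"P5P": (1, 0.8), "NADPH": (2, 0.15)}, 100.0), "cyt"),
        R("NONOX", {"P5P": -3, "F6P": 2, "GAP": 1},
          _enzyme({"P5P": (3, 0.8)}, {"F6P": (2, 0.3), "GAP": (1, 0.1)}, 10.0), "cyt"),
        # anaplerosis, TCA cycle, acetate overflow
        R("PPC", {"PEP": -1, "OAA": 1, "P": 1},
          _enzyme({"PEP": (1, 3.0)}, {"OAA": (1, 0.05), "P": (1, 10.0)}, 100.0,
                  activators={"AcCoA": 0.1}), "cyt", modifiers=("AcCoA",)),
        R("PDH", {"PYR": -1, "NAD": -1, "CoA": -1, "AcCoA": 1, "NADH": 1},
          _enzyme({"PYR": (1, 2.0), "NAD": (1, 0.5), "CoA": (1, 0.1)},
                  {"AcCoA": (1, 0.3), "NADH": (1, 0.1)}, 100.0), "cyt"),
        R("GLT", {"AcCoA": -1, "OAA": -1, "CIT": 1, "CoA": 1},
          _enzyme({"AcCoA": (1, 0.2), "OAA": (1, 0.05)},
                  {"CIT": (1, 1.5), "CoA": (1, 0.5)}, 100.0,
                  inhibitors={"NADH": 0.3}), "cyt", modifiers=("NADH",)),
        R("GS", {"CIT": -1, "AcCoA": -1, "SUC": 1, "OAA": 1, "CoA": 1},
          _enzyme({"CIT": (1, 1.5), "AcCoA": (1, 0.3)},
                  {"SUC": (1, 0.8), "OAA": (1, 0.1), "CoA": (1, 0.5)}, 100.0), "cyt"),
        R("ICD", {"CIT": -1, "NADP": -1, "KG": 1, "NADPH": 1},
          _enzyme({"CIT": (1, 1.0), "NADP": (1, 0.05)},
                  {"KG": (1, 0.5), "NADPH": (1, 0.15)}, 5.0), "cyt"),
        R("KGDH", {"KG": -1, "NAD": -1, "ADP": -1, "P": -1, "SUC": 1, "NADH": 1, "ATP": 1},
          _enzyme({"KG": (1, 0.5), "NAD": (1, 0.5), "ADP": (1, 0.3), "P": (1, 5.0)},
                  {"SUC": (1, 0.8), "NADH": (1, 0.1), "ATP": (1, 2.5)}, 100.0), "cyt"),
        R("SDH", {"SUC": -1, "FAD": -1, "FUM": 1, "FADH2": 1},
          _enzyme({"SUC": (1, 0.8), "FAD": (1, 0.1)},
                  {"FUM": (1, 0.3), "FADH2": (1, 0.05)}, 5.0), "cyt"),
        R("MDH", {"FUM": -1, "NAD": -1, "OAA": 1, "NADH": 1},
          _enzyme({"FUM": (1, 0.3), "NAD": (1, 0.5)},
                  {"OAA": (1, 0.05), "NADH": (1, 0.1)}, 10.0), "cyt"),
        R("ACK", {"AcCoA": -1, "ADP": -1, "P": -1, "ACE_per": 1, "ATP": 1, "CoA": 1},
          rl.mass_action_reversible_law(["AcCoA", "ADP", "P"], ["ACE_per", "ATP", "CoA"], 1.0, 100.0),
          "cyt"),
        # overflow valves: steep low-affinity spill systems (methylglyoxal
        # bypass, sugar-phosphate phosphatases, pyruvate/TCA-intermediate
        # excretion, polyphosphate synthesis); negligible at the reference
        # state, they bound pool accumulation when downstream capacity is low
        R("G6P_SPILL", {"G6P": -1, "P": 1}, rl.overflow_law("G6P", 2.0, 1.0), "cyt"),
        R("P5P_SPILL", {"P5P": -1, "P": 1}, rl.overflow_law("P5P", 1.6, 1.0), "cyt"),
        R("MGS", {"GAP": -1, "PYR": 1, "P": 1}, rl.overflow_law("GAP", 0.2, 1.0), "cyt"),
        R("FBP_SPILL", {"FBP": -1, "P": 2}, rl.overflow_law("FBP", 3.0, 1.0), "cyt"),
        R("PEP_SPILL", {"PEP": -1, "PYR": 1, "P": 1}, rl.overflow_law("PEP", 3.6, 1.0), "cyt"),
        R("PYR_OUT", {"PYR": -1}, rl.overflow_law("PYR", 0.8, 1.0), "cyt"),
        R("CIT_OUT", {"CIT": -1}, rl.overflow_law("CIT", 3.0, 1.0), "cyt"),
        R("KG_OUT", {"KG": -1}, rl.overflow_law("KG", 1.0, 1.0), "cyt"),
        R("SUC_OUT", {"SUC": -1}, rl.overflow_law("SUC", 1.6, 1.0), "cyt"),
        R("PPK", {"P": -1}, rl.overflow_law("P", 20.0, 1.0), "cyt"),
        # oxidative phosphorylation (2 H+/e- pumps, 4 H+/ATP)
        R("NDHI", {"NADH": -1, "Q": -1, "NAD": 1, "QH2": 1, "H_per": 4, "H_cyt": -4},
          rl.oxphos_law("ndhi", quinone, 1.0, 100.0, dph_expr=_dph_expr()), "cyt"),
        R("NDH2", {"NADH": -1, "Q": -1, "NAD": 1, "QH2": 1},
          rl.oxphos_law("ndh2", quinone, 1.0, 100.0), "cyt"),
        R("SQR", {"FADH2": -1, "Q": -1, "FAD": 1, "QH2": 1},
          rl.oxphos_law("sqr", {"FADH2": "FADH2", "FAD": "FAD", "Q": "Q", "QH2": "QH2"}, 1.0, 10.0),
          "cyt"),
        R("CYTBO", {"QH2": -2, "O2": -1, "Q": 2, "H_per": 8, "H_cyt": -8},
          rl.oxphos_law("cytbo", {"QH2": "QH2", "O2": "O2", "Q": "Q"}, 1.0, 1e6,
                        dph_expr=_dph_expr()), "cyt"),
        R("ATP_SYN", {"ADP": -1, "P": -1, "ATP": 1, "H_per": -4, "H_cyt": 4},
          rl.oxphos_law("atp_syn", {"ADP": "ADP", "P": "P", "ATP": "ATP"}, 1.0, 10.0,
                        dph_expr=_dph_expr()), "cyt"),
        # nucleotide interconversion and transhydrogenase
        R("ATP_NGAM", {"ATP": -1, "ADP": 1, "P": 1}, rl.first_order_law("ATP", 1.0), "cyt"),
        R("ADK", {"ATP": -1, "AMP": -1, "ADP": 2},
          rl.mass_action_reversible_law(["ATP", "AMP"], ["ADP", "ADP"], 1.0, 1.0), "cyt"),
        R("CYA", {"ATP": -1, "cAMP": 1, "P": 2}, rl.first_order_law("ATP", 1.0), "cyt"),
        R("DOS", {"cAMP": -1, "AMP": 1}, rl.first_order_law("cAMP", 1.0), "cyt"),
        R("PNT", {"NADH": -1, "NADP": -1, "NAD": 1, "NADPH": 1},
          rl.mass_action_reversible_law(["NADH", "NADP"], ["NAD", "NADPH"], 1.0, 10.0), "cyt"),
        # passive proton leak (bounds the proton-motive force)
        R("H_LEAK", {"H_per": -1, "H_cyt": 1},
          rl.mass_action_reversible_law(["H_per"], ["H_cyt"], 1.0, 1.0), "cyt"),
        # growth
        R("GROWTH",
          {**{sid: -coef for sid, coef in _BIOMASS.items()},
           "CoA": _BIOMASS["AcCoA"], "NADP": _BIOMASS["NADPH"],
           "ADP": _BIOMASS["ATP"],
           # phosphate of the ATP turned over is released; the phosphate of
           # the phosphorylated precursors stays in biomass and is replaced
           # by import (XCH_P)
           "P": _BIOMASS["ATP"]},
          rl.growth_law(
              {sid: REFERENCE_CONCENTRATIONS[sid] / 4.0 for sid in _BIOMASS}, 1.0),
          "cyt"),
    ]


def build_reference_model(parameter_source: str | None = None) -> KineticModel:
    """Build the calibrated reference model.

    With no argument the model is constructed programmatically and
    calibrated so that the chemostat reference state (growth rate 0.1 1/h)
    is an exact steady state.  ``parameter_source`` may alternatively point
    to an SBML file or a plain-text model table (see :mod:`colikinetics.io`),
    e.g. the full-scale published model.
    """
    if parameter_source is not None:
        from . import io as _io

        return _io.read_model(parameter_source)

    comps = [
        Compartment("env", _V_ENV, "environment"),
        Compartment("per", _V_PER, "periplasm"),
        Compartment("cyt", _V_CYT, "cytoplasm"),
    ]
    species = _species()
    reactions = _reactions()
    model = KineticModel(comps, species, reactions, name="ecoli_ccm_reduced")

    F = _reference_fluxes(model)
    missing = set(model.reaction_ids) - set(F)
    if missing:
        raise RuntimeError(f"no reference flux for reactions: {sorted(missing)}")

    # verify the designed flux distribution balances every dynamic species
    c = model.compiled
    Fvec = np.array([F[rid] for rid in model.reaction_ids])
    imbalance = c.S[c.dynamic, :] @ Fvec
    if np.max(np.abs(imbalance)) > 1e-12:
        raise RuntimeError("reference flux distribution is not balanced")

    # calibrate: Vmax such that the reference state carries the target flux
    x_ref = np.array([REFERENCE_CONCENTRATIONS[s.id] for s in species])
    v_unit = model.evaluate_rates(x_ref)  # rates with Vmax = 1
    scale = {}
    for j, rid in enumerate(model.reaction_ids):
        v_target = F[rid] / c.reaction_volumes[j]
        if v_unit[j] == 0:
            raise RuntimeError(f"reaction '{rid}': zero rate at reference state")
        vmax = v_target / v_unit[j]
        if vmax <= 0:
            raise RuntimeError(
                f"reaction '{rid}': calibration yields non-positive Vmax"
            )
        scale[rid] = vmax
    return model.with_vmax_scale(scale)


def excess_glucose_model(model: KineticModel | None = None,
                         glucose_mM: float = EXCESS_GLUCOSE_MM) -> KineticModel:
    """Excess-glucose condition: extracellular glucose clamped (boundary)."""
    if model is None:
        model = build_reference_model()
    return model.with_boundary("GLC_env", glucose_mM)
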
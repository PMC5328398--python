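"""Model and result I/O.

Models are interchanged as SBML Level 3 (including, on a best-effort basis,
externally produced files such as the full-scale *E. coli* central
metabolism model, BioModels MODEL1505110000) or as a plain-text multi-
section TSV dialect that keeps the repository self-contained.  Unknown SBML
constructs (events, algebraic rules, reactions without kinetic laws) are
rejected with a named error rather than silently ignored.

Stage outputs are written as TSV/JSON next to a manifest that records the
configuration and master seed, so a run can be regenerated from its output
directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import sympy as sp

from .model import Compartment, KineticModel, Reaction, Species, SteadyState, Trajectory
from .ratelaws import RateLaw

logger = logging.getLogger(__name__)

__all__ = [
    "read_model",
    "read_model_sbml",
    "write_model_sbml",
    "read_model_table",
    "write_model_table",
    "write_steady_state",
    "write_trajectory",
    "write_matrix",
    "write_manifest",
]

_KIND_HINTS = (
    ("environ", "environment"),
    ("extracell", "environment"),
    ("medium", "environment"),
    ("periplasm", "periplasm"),
    ("cytoplasm", "cytoplasm"),
    ("cytosol", "cytoplasm"),
    ("cell", "cytoplasm"),
)


def read_model(path: str | Path) -> KineticModel:
    """Dispatch on file content: SBML (XML) or the plain-text table dialect."""
    path = Path(path)
    head = path.read_text(errors="ignore")[:200].lstrip()
    if head.startswith("<?xml") or head.startswith("<sbml"):
        return read_model_sbml(path)
    return read_model_table(path)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_MATH_FUNCTIONS = {
    "log10": lambda x: sp.log(x) / sp.log(10),
    "log2": lambda x: sp.log(x) / sp.log(2),
    "ln": sp.log,
    "log": sp.log,
    "exp": sp.exp,
    "sqrt": sp.sqrt,
    "abs": sp.Abs,
    "pow": sp.Pow,
}


def _sympify(formula: str, allowed: Mapping[str, sp.Symbol]) -> sp.Expr:
    local = {**_MATH_FUNCTIONS, **dict(allowed)}
    expr = sp.sympify(formula.replace("^", "**"), locals=local, rational=False)
    unknown = [s.name for s in expr.free_symbols if s.name not in allowed]
    if unknown:
        raise ValueError(f"unknown symbols in kinetic law: {unknown}")
    undef = [f.func.__name__ for f in expr.atoms(sp.Function)
             if isinstance(f, sp.core.function.AppliedUndef)]
    if undef:
        raise ValueError(f"unsupported functions in kinetic law: {sorted(set(undef))}")
    return expr


def read_model_sbml(path: str | Path) -> KineticModel:
    """Read an SBML Level 2/3 model with kinetic laws into a KineticModel.

    Function definitions and initial assignments are expanded; assignment
    rules are substituted into the kinetic laws.  Events and algebraic rules
    are rejected by name.
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValueError(f"malformed SBML in {path}: {msgs[:3]}")
    props = libsbml.ConversionProperties()
    props.addOption("expandFunctionDefinitions", True)
    doc.convert(props)
    props = libsbml.ConversionProperties()
    props.addOption("expandInitialAssignments", True)
    doc.convert(props)
    sbm = doc.getModel()
    if sbm is None:
        raise ValueError(f"no model element in {path}")
    if sbm.getNumEvents() > 0:
        raise ValueError("SBML events are not supported")
    for i in range(sbm.getNumRules()):
        rule = sbm.getRule(i)
        if rule.isAlgebraic() or rule.isRate():
            raise ValueError("algebraic/rate rules are not supported")

    compartments = []
    for i in range(sbm.getNumCompartments()):
        c = sbm.getCompartment(i)
        label = f"{c.getId()} {c.getName()}".lower()
        kind = next((k for hint, k in _KIND_HINTS if hint in label), "cytoplasm")
        vol = c.getSize() if c.isSetSize() else 1.0
        compartments.append(Compartment(c.getId(), vol, kind))

    species = []
    for i in range(sbm.getNumSpecies()):
        s = sbm.getSpecies(i)
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            comp = sbm.getCompartment(s.getCompartment())
            vol = comp.getSize() if comp is not None and comp.isSetSize() else 1.0
            conc = s.getInitialAmount() / vol
        else:
            conc = 0.0
        species.append(
            Species(
                s.getId(), s.getCompartment(), max(conc, 0.0),
                is_boundary=bool(s.getBoundaryCondition() or s.getConstant()),
            )
        )

    sym = {s.id: sp.Symbol(s.id) for s in species}
    global_params = {}
    for i in range(sbm.getNumParameters()):
        p = sbm.getParameter(i)
        global_params[p.getId()] = p.getValue() if p.isSetValue() else np.nan
    for i in range(sbm.getNumCompartments()):
        c = sbm.getCompartment(i)
        global_params.setdefault(c.getId(), c.getSize() if c.isSetSize() else 1.0)

    # assignment rules define derived quantities used inside kinetic laws
    assignments: dict[str, sp.Expr] = {}
    allowed = dict(sym)
    allowed.update({k: sp.Symbol(k) for k in global_params})
    for i in range(sbm.getNumRules()):
        rule = sbm.getRule(i)
        formula = libsbml.formulaToL3String(rule.getMath())
        assignments[rule.getVariable()] = _sympify(
            formula, {**allowed, **{v: sp.Symbol(v) for v in assignments}}
        )

    reactions = []
    for i in range(sbm.getNumReactions()):
        r = sbm.getReaction(i)
        if not r.isSetKineticLaw():
            raise ValueError(f"reaction '{r.getId()}' has no kinetic law")
        kl = r.getKineticLaw()
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        modifiers = tuple(
            r.getModifier(j).getSpecies() for j in range(r.getNumModifiers())
        )
        local = {}
        for j in range(kl.getNumParameters()):
            p = kl.getParameter(j)
            local[p.getId()] = p.getValue()
        for j in range(kl.getNumLocalParameters()):
            p = kl.getLocalParameter(j)
            local[p.getId()] = p.getValue()
        formula = libsbml.formulaToL3String(kl.getMath())
        allowed_here = dict(allowed)
        allowed_here.update({k: sp.Symbol(k) for k in local})
        expr = _sympify(formula, {**allowed_here, **{v: sp.Symbol(v) for v in assignments}})
        # substitute assignment rules, then numeric globals
        for _ in range(len(assignments) + 1):
            before = expr
            expr = expr.xreplace({sp.Symbol(k): v for k, v in assignments.items()})
            if expr == before:
                break
        used_globals = {
            s.name: global_params[s.name]
            for s in expr.free_symbols
            if s.name in global_params and s.name not in sym
        }
        params = {**used_globals, **local}
        params = {
            k: v for k, v in params.items()
            if sp.Symbol(k) in expr.free_symbols
        }
        comp = r.getCompartment() if r.isSetCompartment() else compartments[-1].id
        form = r.getName() if r.getName() else "legacy"
        reactions.append(
            Reaction(
                id=r.getId(), stoichiometry=stoich, modifiers=modifiers,
                rate_law=RateLaw(form=form, expression=expr, parameters=params),
                compartment=comp,
            )
        )
    name = sbm.getId() or Path(path).stem
    return KineticModel(compartments, species, reactions, name=name)


def write_model_sbml(model: KineticModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 Version 2.

    Conventions: rates are concentration/time in the reaction's compartment
    (stored in the reaction's ``compartment`` attribute); the rate-law form
    is stored in the reaction's ``name``.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sbm = doc.createModel()
    sbm.setId(model.name)
    for c in model.compartments:
        sc = sbm.createCompartment()
        sc.setId(c.id)
        sc.setName(c.kind)
        sc.setSize(c.volume)
        sc.setConstant(True)
        sc.setSpatialDimensions(3)
    for s in model.species:
        ss = sbm.createSpecies()
        ss.setId(s.id)
        ss.setCompartment(s.compartment)
        ss.setInitialConcentration(s.concentration)
        ss.setBoundaryCondition(bool(s.is_boundary))
        ss.setConstant(False)
        ss.setHasOnlySubstanceUnits(False)
    for r in model.reactions:
        sr = sbm.createReaction()
        sr.setId(r.id)
        sr.setName(r.rate_law.form)
        sr.setReversible(True)
        sr.setCompartment(r.compartment)
        for sid, coef in r.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        for sid in r.modifiers:
            mod = sr.createModifier()
            mod.setSpecies(sid)
        kl = sr.createKineticLaw()
        for pname, pval in r.rate_law.parameters.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(pval))
        formula = sp.sstr(r.rate_law.expression).replace("**", "^")
        math = libsbml.parseL3Formula(formula)
        if math is None:
            raise ValueError(f"reaction '{r.id}': cannot encode rate law")
        kl.setMath(math)
    Path(path).write_text(libsbml.writeSBMLToString(doc))


# ---------------------------------------------------------------------------
# Plain-text table dialect
# ---------------------------------------------------------------------------

def write_model_table(model: KineticModel, path: str | Path) -> None:
    """Multi-section TSV: compartments, species, reactions, parameters.

    Units: volumes L (relative), concentrations mM, rates mM/s in the
    reaction's compartment; rate expressions are sympy-parseable strings in
    species ids and parameter names.
    """
    lines = [
        "# kinetic model table v1 (concentrations mM, time s, rates mM/s)",
        f"# model\t{model.name}",
        "[compartments]",
        "id\tvolume\tkind",
    ]
    for c in model.compartments:
        lines.append(f"{c.id}\t{float(c.volume)!r}\t{c.kind}")
    lines += ["[species]", "id\tcompartment\tconcentration\tboundary"]
    for s in model.species:
        lines.append(f"{s.id}\t{s.compartment}\t{float(s.concentration)!r}\t{int(s.is_boundary)}")
    lines += ["[reactions]", "id\tcompartment\tform\tstoichiometry\tmodifiers\texpression"]
    for r in model.reactions:
        st = ",".join(f"{sid}:{float(coef)!r}" for sid, coef in r.stoichiometry.items())
        mods = ",".join(r.modifiers)
        expr = sp.sstr(r.rate_law.expression)
        lines.append(f"{r.id}\t{r.compartment}\t{r.rate_law.form}\t{st}\t{mods}\t{expr}")
    lines += ["[parameters]", "reaction\tparameter\tvalue\tunit\tsource"]
    unit = {"Vmax": "mM/s", "Keq": "1"}
    for r in model.reactions:
        for pname, pval in r.rate_law.parameters.items():
            u = unit.get(pname.split("_")[0], "mM")
            lines.append(f"{r.id}\t{pname}\t{float(pval)!r}\t{u}\tmodel")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_table(path: str | Path) -> KineticModel:
    """Read the plain-text dialect written by :func:`write_model_table`."""
    section = None
    header = False
    name = Path(path).stem
    comps, species, rxn_rows = [], [], []
    params: dict[str, dict[str, float]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("# model\t"):
            name = line.split("\t", 1)[1]
            continue
        if line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            header = True
            continue
        if header:
            header = False
            continue
        cells = line.split("\t")
        if section == "compartments":
            comps.append(Compartment(cells[0], float(cells[1]), cells[2]))
        elif section == "species":
            species.append(
                Species(cells[0], cells[1], float(cells[2]), bool(int(cells[3])))
            )
        elif section == "reactions":
            rxn_rows.append(cells)
        elif section == "parameters":
            params.setdefault(cells[0], {})[cells[1]] = float(cells[2])
        else:
            raise ValueError(f"unknown section '{section}' in {path}")
    if not comps or not species or not rxn_rows:
        raise ValueError(f"incomplete model table {path}")
    reactions = []
    for rid, comp, form, st, mods, expr_str in rxn_rows:
        stoich = {}
        for item in st.split(","):
            sid, coef = item.rsplit(":", 1)
            stoich[sid] = float(coef)
        p = params.get(rid, {})
        allowed = {s.id: sp.Symbol(s.id) for s in species}
        allowed.update({k: sp.Symbol(k) for k in p})
        expr = _sympify(expr_str, allowed)
        reactions.append(
            Reaction(
                id=rid, stoichiometry=stoich,
                modifiers=tuple(m for m in mods.split(",") if m),
                rate_law=RateLaw(form=form, expression=expr, parameters=p),
                compartment=comp,
            )
        )
    return KineticModel(comps, species, reactions, name=name)


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_steady_state(state: SteadyState, path: str | Path) -> None:
    """TSV with a concentrations block (mM) and a fluxes block (mM/s)."""
    lines = ["# steady state (concentrations mM; fluxes mM/s)",
             f"# converged\t{state.converged}",
             f"# residual_norm\t{float(state.residual_norm)!r}",
             "kind\tid\tvalue"]
    for sid, x in zip(state.species_ids, state.concentrations):
        lines.append(f"concentration\t{sid}\t{float(x)!r}")
    for rid, v in zip(state.reaction_ids, state.fluxes):
        lines.append(f"flux\t{rid}\t{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Species x time TSV (mM; first column time in s)."""
    df = pd.DataFrame(traj.concentrations.T, columns=list(traj.species_ids))
    df.insert(0, "time_s", traj.t)
    df.to_csv(path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t")


def write_manifest(out_dir: str | Path, config: Mapping, seed: int | None) -> Path:
    """JSON manifest: config, master seed, timestamps; enables regeneration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: _jsonable(v) for k, v in config.items()},
        "seed": seed,
        "written_at_unix": time.time(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
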
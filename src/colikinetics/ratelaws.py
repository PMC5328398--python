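"""Rate laws of the central carbon and energy metabolism model.

Every rate law is represented symbolically (a :mod:`sympy` expression in
species concentrations and named kinetic parameters) so that models can be
compiled to fast numeric functions, differentiated exactly, and serialized
to SBML or the plain-text table dialect.

The bespoke forms are those of the oxidative-phosphorylation chain
(NDH-I/NDH-II dehydrogenases, succinate:quinone reductase, cytochrome *bo*
oxidase, ATP synthase), the trans-membrane pH difference that attenuates the
proton pumps, and the multiplicative-saturation growth law.  Generic forms
(reversible/irreversible Michaelis-Menten, reversible mass action) cover the
remaining enzymatic and transport steps.

Units: concentrations mM, time s, rates mM/s referenced to the reaction's
compartment; ``Vmax`` mM/s, ``Km`` mM, ``Keq`` dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp

__all__ = [
    "RateLaw",
    "delta_ph",
    "delta_ph_expr",
    "rate_oxphos",
    "rate_growth",
    "rate_exchange_porin",
    "oxphos_law",
    "growth_law",
    "reversible_mm_law",
    "irreversible_mm_law",
    "mass_action_reversible_law",
    "convenience_law",
    "overflow_law",
    "constant_flux_law",
    "first_order_law",
    "custom_law",
    "OXPHOS_FORMS",
]

#: Forms of the oxidative-phosphorylation chain with their own rate equations.
OXPHOS_FORMS = ("ndhi", "ndh2", "sqr", "cytbo", "atp_syn")


@dataclass(frozen=True)
class RateLaw:
    """A parameterized symbolic rate expression.

    Parameters appearing in ``expression`` are free symbols whose names are
    keys of ``parameters``; all other free symbols must be species ids.
    """

    form: str
    expression: sp.Expr
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        free = {s.name for s in self.expression.free_symbols}
        missing = [p for p in self.parameters if p not in free]
        if missing:
            raise ValueError(
                f"rate law '{self.form}': parameters {missing} do not appear "
                "in the expression"
            )

    @property
    def species_names(self) -> tuple[str, ...]:
        """Names of species symbols (free symbols that are not parameters)."""
        return tuple(
            sorted(
                s.name
                for s in self.expression.free_symbols
                if s.name not in self.parameters
            )
        )

    def evaluate(self, concentrations: Mapping[str, float]) -> float:
        """Numeric rate at the given concentrations (parameters bound)."""
        subs = {sp.Symbol(k): v for k, v in self.parameters.items()}
        subs.update({sp.Symbol(k): v for k, v in concentrations.items()})
        val = self.expression.xreplace(subs)
        return float(val)


# ---------------------------------------------------------------------------
# Trans-membrane pH difference
# ---------------------------------------------------------------------------

def delta_ph(h_cytoplasm: float, h_periplasm: float) -> float:
    """pH difference across the inner membrane, log10(H_cyt / H_per).

    Defined with the decadic logarithm because pH itself is; one order of
    magnitude in the proton ratio is one pH unit.  Both concentrations must
    be strictly positive.
    """
    if h_cytoplasm <= 0 or h_periplasm <= 0:
        raise ValueError(
            "proton concentrations must be > 0, got "
            f"h_cytoplasm={h_cytoplasm}, h_periplasm={h_periplasm}"
        )
    return math.log10(h_cytoplasm / h_periplasm)


def delta_ph_expr(h_cyt: sp.Symbol, h_per: sp.Symbol) -> sp.Expr:
    """Symbolic log10(H_cyt / H_per)."""
    return sp.log(h_cyt / h_per) / sp.log(10)


# ---------------------------------------------------------------------------
# Oxidative phosphorylation
# ---------------------------------------------------------------------------

def _oxphos_expression(form: str, sym: Mapping[str, sp.Expr]) -> sp.Expr:
    vmax = sym["Vmax"]
    keq = sym["Keq"]
    dph = sym.get("dpH")
    if form == "ndhi":
        return (
            vmax
            * (1 / (1 + dph**2))
            * (sym["NADH"] * sym["Q"] - sym["NAD"] * sym["QH2"] / keq)
        )
    if form == "ndh2":
        return vmax * (sym["NADH"] * sym["Q"] - sym["NAD"] * sym["QH2"] / keq)
    if form == "sqr":
        return vmax * (sym["FADH2"] * sym["Q"] - sym["FAD"] * sym["QH2"] / keq)
    if form == "cytbo":
        return (
            vmax
            * (1 / (1 + dph**2))
            * (sym["QH2"] ** 2 * sym["O2"] - sym["Q"] ** 2 / keq)
        )
    if form == "atp_syn":
        return (
            vmax
            * (dph**4 / (1 + dph**4))
            * (sym["ADP"] * sym["P"] - sym["ATP"] / keq)
        )
    raise ValueError(f"unknown oxidative-phosphorylation form '{form}'")


_OXPHOS_SPECIES = {
    "ndhi": ("NADH", "Q", "NAD", "QH2"),
    "ndh2": ("NADH", "Q", "NAD", "QH2"),
    "sqr": ("FADH2", "Q", "FAD", "QH2"),
    "cytbo": ("QH2", "O2", "Q"),
    "atp_syn": ("ADP", "P", "ATP"),
}

_DPH_FORMS = ("ndhi", "cytbo", "atp_syn")


def rate_oxphos(
    form: str,
    concentrations: Mapping[str, float],
    params: Mapping[str, float],
) -> float:
    """Numeric rate of one oxidative-phosphorylation step (mM/s).

    ``concentrations`` supplies the cofactor pools by their conventional
    names (NADH, NAD, Q, QH2, FADH2, FAD, O2, ADP, ATP, P) plus ``dpH`` for
    the proton-pump forms; ``params`` supplies Vmax and Keq.
    """
    if form not in OXPHOS_FORMS:
        raise ValueError(f"unknown oxidative-phosphorylation form '{form}'")
    for name in ("Vmax", "Keq"):
        if name not in params:
            raise KeyError(f"missing parameter '{name}' for form '{form}'")
    if params["Vmax"] < 0:
        raise ValueError("Vmax must be >= 0")
    if params["Keq"] <= 0:
        raise ValueError("Keq must be > 0")
    needed = _OXPHOS_SPECIES[form] + (("dpH",) if form in _DPH_FORMS else ())
    sym: dict[str, sp.Expr] = {
        "Vmax": sp.Float(params["Vmax"]),
        "Keq": sp.Float(params["Keq"]),
    }
    for name in needed:
        if name not in concentrations:
            raise KeyError(f"missing concentration '{name}' for form '{form}'")
        if name != "dpH" and concentrations[name] < 0:
            raise ValueError(f"negative concentration for '{name}'")
        sym[name] = sp.Float(concentrations[name])
    return float(_oxphos_expression(form, sym))


def oxphos_law(
    form: str,
    species: Mapping[str, str],
    vmax: float,
    keq: float,
    dph_expr: sp.Expr | None = None,
) -> RateLaw:
    """Symbolic oxidative-phosphorylation rate law.

    ``species`` maps the canonical cofactor roles (e.g. ``"NADH"``) to the
    species ids used by the model.  For the proton-pump forms ``dph_expr``
    must be the symbolic pH-difference expression in the model's proton
    species (its own free symbols are treated as species).
    """
    if form not in OXPHOS_FORMS:
        raise ValueError(f"unknown oxidative-phosphorylation form '{form}'")
    sym: dict[str, sp.Expr] = {
        "Vmax": sp.Symbol("Vmax"),
        "Keq": sp.Symbol("Keq"),
    }
    for role in _OXPHOS_SPECIES[form]:
        sym[role] = sp.Symbol(species[role])
    if form in _DPH_FORMS:
        if dph_expr is None:
            raise ValueError(f"form '{form}' requires a dpH expression")
        sym["dpH"] = dph_expr
    expr = _oxphos_expression(form, sym)
    return RateLaw(form=form, expression=expr, parameters={"Vmax": vmax, "Keq": keq})


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def rate_growth(
    building_blocks: Sequence[tuple[float, float]], vmax: float
) -> float:
    """Specific growth rate mu = Vmax * prod_i S_i / (S_i + Km_i)  (1/s).

    Each building block contributes one saturable factor, so growth rises
    monotonically with every precursor pool, saturates at Vmax, and vanishes
    when any pool is exhausted.
    """
    if len(building_blocks) == 0:
        raise ValueError("growth law requires at least one building block")
    mu = vmax
    for s_i, km_i in building_blocks:
        if km_i <= 0:
            raise ValueError(f"Km must be > 0, got {km_i}")
        if s_i < 0:
            raise ValueError(f"concentration must be >= 0, got {s_i}")
        mu *= s_i / (s_i + km_i)
    return mu


def growth_law(precursors: Mapping[str, float], vmax: float) -> RateLaw:
    """Multiplicative-saturation growth law over the given precursor pools.

    ``precursors`` maps species ids to their Km (mM); the per-precursor Km
    parameters are named ``Km_<species>``.
    """
    if not precursors:
        raise ValueError("growth law requires at least one building block")
    expr: sp.Expr = sp.Symbol("Vmax")
    params: dict[str, float] = {"Vmax": vmax}
    for sid, km in precursors.items():
        if km <= 0:
            raise ValueError(f"Km must be > 0, got {km} for {sid}")
        km_sym = sp.Symbol(f"Km_{sid}")
        s = sp.Symbol(sid)
        expr = expr * s / (s + km_sym)
        params[f"Km_{sid}"] = km
    return RateLaw(form="growth_multiplicative", expression=expr, parameters=params)


# ---------------------------------------------------------------------------
# Generic enzymatic / transport forms
# ---------------------------------------------------------------------------

def rate_exchange_porin(
    s_out: float, s_in: float, params: Mapping[str, float]
) -> float:
    """Porin-facilitated diffusion across the outer membrane (mM/s).

    Reversible Michaelis-Menten: saturable in both directions, zero at the
    Keq-defined equilibrium, sign following the concentration gradient.
    """
    km = params["Km"]
    if km <= 0:
        raise ValueError(f"Km must be > 0, got {km}")
    if s_out < 0 or s_in < 0:
        raise ValueError("concentrations must be >= 0")
    vmax = params["Vmax"]
    keq = params.get("Keq", 1.0)
    return vmax * (s_out - s_in / keq) / (km + s_out + s_in / keq)


def reversible_mm_law(
    substrate: str, product: str, vmax: float, km: float, keq: float
) -> RateLaw:
    """Reversible uni-uni Michaelis-Menten, v = Vmax (S - P/Keq)/(Km + S + P/Keq)."""
    if km <= 0:
        raise ValueError("Km must be > 0")
    s, p = sp.Symbol(substrate), sp.Symbol(product)
    vm, kms, keqs = sp.Symbol("Vmax"), sp.Symbol("Km"), sp.Symbol("Keq")
    expr = vm * (s - p / keqs) / (kms + s + p / keqs)
    return RateLaw(
        form="reversible_michaelis_menten",
        expression=expr,
        parameters={"Vmax": vmax, "Km": km, "Keq": keq},
    )


def irreversible_mm_law(
    substrates: Mapping[str, float],
    vmax: float,
    inhibitors: Mapping[str, float] | None = None,
    activators: Mapping[str, float] | None = None,
) -> RateLaw:
    """Irreversible Michaelis-Menten, multiplicative over substrates.

    Optional hyperbolic modifier terms: each inhibitor I contributes
    1/(1 + I/Ki_I), each activator A contributes A/(Ka_A + A).
    """
    expr: sp.Expr = sp.Symbol("Vmax")
    params: dict[str, float] = {"Vmax": vmax}
    for sid, km in substrates.items():
        if km <= 0:
            raise ValueError(f"Km must be > 0, got {km} for {sid}")
        s, kms = sp.Symbol(sid), sp.Symbol(f"Km_{sid}")
        expr = expr * s / (s + kms)
        params[f"Km_{sid}"] = km
    for sid, ki in (inhibitors or {}).items():
        i, kis = sp.Symbol(sid), sp.Symbol(f"Ki_{sid}")
        expr = expr / (1 + i / kis)
        params[f"Ki_{sid}"] = ki
    for sid, ka in (activators or {}).items():
        a, kas = sp.Symbol(sid), sp.Symbol(f"Ka_{sid}")
        expr = expr * a / (a + kas)
        params[f"Ka_{sid}"] = ka
    return RateLaw(form="irreversible_michaelis_menten", expression=expr, parameters=params)


def convenience_law(
    substrates: Mapping[str, tuple[float, float]],
    products: Mapping[str, tuple[float, float]],
    vmax: float,
    keq: float,
    inhibitors: Mapping[str, float] | None = None,
    activators: Mapping[str, float] | None = None,
) -> RateLaw:
    """Reversible convenience kinetics (common modular rate law).

    ``substrates`` / ``products`` map species ids to ``(stoichiometric
    order, Km)``.  The rate is

        v = Vmax * prod_s (S/KmS)^n * (1 - Gamma/Keq) / D * modifiers

    with reaction quotient Gamma = prod_p P^m / prod_s S^n and denominator
    D = prod_s (1+S/KmS)^n + prod_p (1+P/KmP)^m - 1.  The rate vanishes
    exactly at thermodynamic equilibrium (Gamma = Keq) and product
    accumulation throttles the enzyme through both the quotient and the
    binding-competition denominator, which is what keeps metabolite pools
    bounded when downstream capacity is low.  Optional hyperbolic
    inhibitor/activator factors as in :func:`irreversible_mm_law`.
    """
    if keq <= 0:
        raise ValueError("Keq must be > 0")
    params: dict[str, float] = {"Vmax": vmax, "Keq": keq}
    num_sat: sp.Expr = sp.Integer(1)
    gamma_num: sp.Expr = sp.Integer(1)
    gamma_den: sp.Expr = sp.Integer(1)
    d_sub: sp.Expr = sp.Integer(1)
    d_prod: sp.Expr = sp.Integer(1)
    for sid, (n, km) in substrates.items():
        if km <= 0:
            raise ValueError(f"Km must be > 0, got {km} for {sid}")
        s, kms = sp.Symbol(sid), sp.Symbol(f"Km_{sid}")
        params[f"Km_{sid}"] = km
        num_sat *= (s / kms) ** int(n)
        gamma_den *= s ** int(n)
        d_sub *= (1 + s / kms) ** int(n)
    for sid, (m, km) in products.items():
        if km <= 0:
            raise ValueError(f"Km must be > 0, got {km} for {sid}")
        p, kmp = sp.Symbol(sid), sp.Symbol(f"Km_{sid}")
        params[f"Km_{sid}"] = km
        gamma_num *= p ** int(m)
        d_prod *= (1 + p / kmp) ** int(m)
    keq_sym = sp.Symbol("Keq")
    expr = (
        sp.Symbol("Vmax")
        * num_sat
        * (1 - gamma_num / (gamma_den * keq_sym))
        / (d_sub + d_prod - 1)
    )
    for sid, ki in (inhibitors or {}).items():
        expr = expr / (1 + sp.Symbol(sid) / sp.Symbol(f"Ki_{sid}"))
        params[f"Ki_{sid}"] = ki
    for sid, ka in (activators or {}).items():
        a = sp.Symbol(sid)
        expr = expr * a / (a + sp.Symbol(f"Ka_{sid}"))
        params[f"Ka_{sid}"] = ka
    return RateLaw(form="convenience_reversible", expression=expr, parameters=params)


def mass_action_reversible_law(
    substrates: Sequence[str], products: Sequence[str], vmax: float, keq: float
) -> RateLaw:
    """Reversible mass action, v = Vmax (prod(S) - prod(P)/Keq)."""
    fwd = sp.Integer(1)
    for sid in substrates:
        fwd *= sp.Symbol(sid)
    back = sp.Integer(1)
    for sid in products:
        back *= sp.Symbol(sid)
    expr = sp.Symbol("Vmax") * (fwd - back / sp.Symbol("Keq"))
    return RateLaw(
        form="mass_action_reversible",
        expression=expr,
        parameters={"Vmax": vmax, "Keq": keq},
    )


def overflow_law(species: str, threshold: float, vmax: float) -> RateLaw:
    """Quartic overflow valve, v = Vmax * (S / K)^4 (non-saturating).

    Represents low-affinity spill systems (sugar-phosphate phosphatases,
    methylglyoxal bypass, metabolite excretion, polyphosphate synthesis)
    that are negligible near the reference pool size K but engage steeply
    when a pool overshoots, preventing unbounded accumulation when
    downstream enzymatic capacity is limiting.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    expr = sp.Symbol("Vmax") * (sp.Symbol(species) / sp.Symbol("K")) ** 4
    return RateLaw(form="overflow_quartic", expression=expr,
                   parameters={"Vmax": vmax, "K": threshold})


def constant_flux_law(vmax: float) -> RateLaw:
    """Zero-order supply (e.g. chemostat feed), v = Vmax."""
    # Multiply by Vmax/Vmax == 1?  No: the expression must contain the symbol.
    return RateLaw(form="constant_flux", expression=sp.Symbol("Vmax"), parameters={"Vmax": vmax})


def first_order_law(species: str, vmax: float) -> RateLaw:
    """First-order consumption (e.g. dilution/washout), v = Vmax * S."""
    expr = sp.Symbol("Vmax") * sp.Symbol(species)
    return RateLaw(form="first_order", expression=expr, parameters={"Vmax": vmax})


def custom_law(form: str, expression: str | sp.Expr, parameters: Mapping[str, float]) -> RateLaw:
    """A transcribed ('legacy') rate law given as a sympy-parseable expression."""
    if isinstance(expression, str):
        expression = sp.sympify(expression, rational=False)
    return RateLaw(form=form, expression=expression, parameters=dict(parameters))
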
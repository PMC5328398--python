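# Methods

## Model formulation

The kinetic model is a deterministic ODE system over three compartments:
environment, periplasm and cytoplasm, with the periplasm fixed at 20% of
the total cell volume.  Species are concentrations in mM; each reaction's
rate (mM/s) refers to the compartment the reaction is assigned to, and the
right-hand side rescales cross-compartment transport by the volume ratio:

    dx_i/dt = (V_r(j) / V_c(i)) · Σ_j S_ij v_j(x, p).

Boundary species (dissolved O₂, cytoplasmic H⁺ at pH 7, the medium phosphate
reservoir, and — in the excess-glucose condition — extracellular glucose)
have a frozen right-hand side; their clamped value is part of the model's
condition, and is never overridden by a caller's initial guess.

### Rate laws

* **Oxidative phosphorylation.**  NDH-I, NDH-II, SQR, cytochrome *bo*
  oxidase and ATP synthase use mass-action driving terms
  (substrates − products/Keq).  The proton pumps (NDH-I, cytochrome *bo*)
  are attenuated by 1/(1+ΔpH²) and the synthase activated by
  ΔpH⁴/(1+ΔpH⁴), with ΔpH = log₁₀(H⁺_cyt / H⁺_per).  The decadic logarithm
  is used because ΔpH is a pH difference and pH is defined with log₁₀.
  Both modulation terms are even in ΔpH, so the only sign-sensitive
  behavior enters through the Keq-driven mass-action terms.  Proton
  bookkeeping follows 2 H⁺/e⁻ for the pumps and 4 H⁺/ATP for the synthase,
  tracked as explicit flows of periplasmic H⁺; a passive proton leak
  (mass-action H⁺_per ⇌ H⁺_cyt) is included because the pump/synthase pair
  alone has no equilibrium — without a leak the proton gradient of a state
  with mismatched pump and synthase capacity grows without bound, since the
  1/(1+ΔpH²) attenuation decays only logarithmically in H⁺_per.
* **Growth.**  A single reaction consumes all biomass precursors (G6P, P5P,
  PEP, PYR, AcCoA, OAA, KG, NADPH, ATP) in fixed stoichiometric proportions
  at rate μ = Vmax·∏ S_i/(S_i+Km_i).  Precursor Km values are set to a
  quarter of the reference pool, which puts the reference state at 80%
  saturation per factor and gives a ceiling of ≈ 0.75 h⁻¹.  The
  multiplicative form makes growth monotone in every pool, saturating, and
  zero whenever any pool empties.
* **Enzymatic steps** use reversible convenience kinetics (the common
  modular rate law): v = Vmax·∏(S/KmS)·(1−Γ/Keq)/D with the reaction
  quotient Γ and a denominator carrying both substrate and product binding.
  Keq values are assigned as a fixed thermodynamic displacement relative to
  the reference-state quotient: 100× for the physiologically irreversible
  steps (PTS, PFK, PYK, PPS, ZWF, PPC, PDH, GLT, GS, KGDH) and 1.2–20× for
  the near-equilibrium ones (PGI, FBA, GDH, NONOX, ICD, SDH, MDH).  Product
  binding plus the thermodynamic term is what bounds metabolite pools when
  a downstream capacity is randomly scaled down — the "thermodynamic
  regulation" component of metabolic regulation.
* **Exchange** across the outer membrane (glucose, acetate, phosphate) is
  porin-facilitated diffusion, a reversible Michaelis–Menten form that is
  saturable in both directions and vanishes at the Keq-defined equilibrium.
* **Overflow valves.**  Quartic overflow kinetics v = Vmax·(S/K)⁴ represent
  the low-affinity spill systems real cells use against metabolite
  overaccumulation: the methylglyoxal bypass for triose phosphates,
  sugar-phosphate phosphatases, pyruvate and TCA-intermediate excretion,
  and polyphosphate synthesis for phosphate.  Their reference fluxes are
  pinned at ~10⁻⁴ of the carrying pathway, so they are silent within an
  order of magnitude of the reference pools and engage steeply beyond
  roughly ten-fold overshoot.  Without them, a random enzyme ensemble
  produces steady states with pools in the molar range (a producer scaled
  up tenfold against a saturable consumer has no bounded balance point),
  which is both unphysiological and numerically hostile.

### Calibration by construction

The reference condition is a glucose-limited chemostat at dilution rate
D = 0.1 h⁻¹.  Calibration proceeds in three steps: (1) reference
concentrations are fixed at physiological magnitudes (total cytoplasmic
pool 26.7 mM); (2) a reference flux distribution is fixed by pinning the
physiology-defining fluxes (glucose uptake, PPP split, acetate overflow,
NDH-I share, proton leak, valve fluxes, growth = D) and solving the
remaining fluxes uniquely from the species balances S·F = 0; (3) every Vmax
is solved so that the reference state carries exactly the reference flux.
The reference state is therefore an exact steady state by construction
(residual ~10⁻¹⁴ mM/s), and linearly stable (verified numerically; the only
zero modes are the conserved moieties).

The model is synthetic: parameters are not transcribed from a published
set.  Its purpose is to reproduce the *architecture and analysis chain* of
full-scale kinetic models of *E. coli* central metabolism at a size where
every analysis runs in minutes.  Structural differences from the
full-scale published model (BioModels MODEL1505110000, loadable through
`colikinetics.io.read_model_sbml`): 45 vs 68 reactions, 35 vs 62
metabolites, 4 vs 34 long-range (modifier-only) regulatory interactions,
lumped glycolysis/PPP/TCA segments, and overflow valves in place of the
full regulatory web.  Consequently its *numerical* control coefficients
and coupling strengths are its own; what carries over is the qualitative
phenomenology (environment-dominated control, distributed enzyme control,
growth–uptake coupling under random enzyme levels, pool homeostasis).

## Numerics

* **Integration**: LSODA with relative tolerance 10⁻⁶ and absolute
  tolerance 10⁻⁸ (mM); the analytic Jacobian is supplied from the symbolic
  rate laws.  Concentrations are floored at 10⁻³⁰ mM inside rate
  evaluations to guard the logarithmic ΔpH terms against transient
  negative integrator excursions.
* **Steady states**: damped Newton on the reduced system — conserved
  moieties (left null space of the amount stoichiometry; adenylate,
  NAD(H), NADP(H), FAD(H₂), quinone and CoA families in the reference
  model) are eliminated, dependent species recovered from the conserved
  totals — with backtracking line search constrained to positive
  concentrations.  When Newton stalls, a ladder of stiff integrations
  (horizons 10² … 10⁸ s) runs with a Newton polish after each stage.  A
  state converges when |dx_i/dt| ≤ 10⁻⁸ + 10⁻⁶·min(x_i, 10³) for every
  dynamic species; the cap on the relative term prevents an unbounded
  divergence (e.g. chemostat washout, where substrate accumulates forever
  under constant feed) from being declared converged once the pool is
  large.  Each solve carries a right-hand-side evaluation budget (default
  40,000 in ensembles) so hopeless samples cost bounded time and are
  reported as non-converged rather than hanging a run.
* **Control coefficients**: central differences on ln Vmax with relative
  step 10⁻³, warm-started from the reference state; validated by the
  summation theorems (residuals ~5·10⁻⁴ on the reference model) and
  against a two-sided 1% secant oracle on toys.  Steps whose perturbed
  states fail to converge are retried with a halved step, then reported as
  failed columns.  Fluxes below 10⁻¹² mM/s are excluded from scaled flux
  control (∂lnJ undefined) and listed in the result's metadata.
* **Hit-and-run sampling** operates in the null-space parameterization of
  S·v = 0, from a Chebyshev-style interior point, with warm-up 10·dim and
  thinning dim steps.  Uniformity is validated on an analytic polytope (a
  flux triangle whose marginals are uniform on the 2-simplex) rather than
  asserted.  Flux bounds must be finite; for the reference polytope the
  caps are 10× the largest amount flux observed in the kinetic ensemble
  per reaction.
* **Particle swarm**: 50 particles, inertia 0.7, cognitive and social
  weights 1.5 (standard settings; exposed as arguments), reflective bound
  handling, deterministic under a seed.  Fitting searches log₁₀ parameter
  space because the admissible ranges span 5–10 decades.  Simulation
  failures inside the objective return a 10³⁰ penalty plus a
  distance-to-box-center term; the penalty must dominate any finite
  weighted SSE, which reaches ~10²⁵ for feasible-but-poor fits under tight
  sigmas.  Kinetic boundary searches seed one particle at the reference
  enzyme vector, which guarantees the envelope contains the reference
  state and anchors the search in the feasible region.
* **Ensemble protocol**: every random-enzyme steady state is solved from
  the condition's reference state.  The model is multistable, so the basin
  reached depends on the initial state; chaining solves through the
  previous sample's solution would correlate the ensemble and make its
  statistics depend on sample order.  The reference start is also the
  physical protocol: enzyme levels change in a cell sitting at the
  reference state.
* **Random streams**: every stochastic component (enzyme sampling,
  robustness resampling, noise generation, swarm) spawns per-sample
  substreams from a single master seed, so results are independent of
  evaluation order and reproducible from the manifest.

## Analysis conventions

* "Enzymes" vs "environment" in control summaries: the glucose supply
  reaction (GLC_FEED) is the environment step; all other steps count as
  enzymes.
* "Sum of fluxes" is Σ|amount flux| over intracellular reactions (feed,
  washout and exchange reactions excluded); absolute values keep
  reversible steps from cancelling.
* Cofactor production rates are *gross* (sum of stoichiometry-weighted
  producing fluxes): at steady state net production is ~0 by definition,
  so the gross rate is the informative quantity.
* Relative pathway fluxes are pathway flux per glucose uptake; yields are
  rates per glucose uptake and are undefined (excluded from rank
  statistics) where uptake is zero.
* Enzyme cost is Σ over reactions of scale factor × enzyme concentration
  (μM) × protein length (amino acids); reactions without a tabulated
  concentration use the 18 μM average.  The packaged table
  (`data/enzyme_costs.tsv`) holds synthetic values at physiological
  magnitudes.
* Mutual information uses equal-frequency binning with ⌊n^(1/3)⌋ bins
  (capped at 30) and the plug-in estimator, reported in nats; the total
  intracellular pool sums cytoplasmic species only.
* Homeostasis is the fraction of ensemble steady states whose total pool
  stays within k-fold (default 3) of the calibrated total.

## Synthetic data

The generators provide every fixture the tests need, deterministically
from a seed: boundary-fed linear chains (mass-action or saturable) and a
branch point with closed-form steady states; a closed reversible
isomerization with an exponential analytic solution; calibration datasets
with per-point σ and Gaussian noise matched to the weighted objective (so
the objective at the true parameters is ~χ²); and validation flux tables
that emulate literature compilations of growth/uptake/respiration
measurements by subsampling a kinetic ensemble under multiplicative
lognormal noise (default 254 rows, the size of typical compilations).
What passing tests on these fixtures establish is internal correctness —
solver accuracy against closed forms, estimator limits, sampler
uniformity — not agreement with any real measurement: the synthetic data
inherit the model's own rate laws and contain none of the systematic
errors, condition heterogeneity, or non-steady-state effects of real
cultivation data.

## Scale of the shipped analyses

The acceptance script runs the ensemble at n = 1,200 enzyme vectors,
the polytope sampler at n = 4,000 (10,000 for the analytic validation),
a 3-point envelope grid, and a 3-parameter recovery study — sizes chosen
so the whole chain reproduces in minutes on one CPU.  Ensemble statistics
at this size carry Monte-Carlo error of roughly ±0.03 on rank
correlations and ±2 percentage points on the homeostasis fraction.

## Known limitations

* The kinetic growth envelope is much narrower than the stoichiometric
  one in this reduced model (the growth law's Vmax ceiling binds long
  before the carbon-yield limit of the polytope), so the near-coincidence
  of the two solution spaces seen in full-scale models is not reproduced;
  the envelope ratio is reported honestly by the acceptance script.
* The swarm-based envelope is approximate at its corners; points are
  flagged when the pinned variable misses its grid value by more than 2%.
* Proton bookkeeping is reduced to pump/synthase/leak flows of
  periplasmic H⁺ against a clamped cytoplasmic pH; there is no buffering
  and no charge balance.
* Growth does not dilute intracellular pools (no μ·x term); at the
  reference dilution rate the neglected term is ~10⁻³ of typical fluxes.
* The stoichiometric model's reversibility is inferred from rate-law
  forms, not from thermodynamic data.
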
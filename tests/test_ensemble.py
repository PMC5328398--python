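"""Kinetic ensembles, flux-space sampling, and solution-space boundaries."""

import numpy as np
import pytest
import scipy.stats as st

from colikinetics import ensemble as ens
from colikinetics import synthetic as syn
from colikinetics.model import ABS_TOL, REL_TOL


class TestEnzymeSampling:
    def test_degenerate_bounds_give_unit_factors(self, ref_model):
        samples = ens.sample_enzyme_levels(ref_model, 5, lo=1.0, hi=1.0, seed=0)
        for s in samples:
            assert np.all(s.factors == 1.0)

    def test_log_uniform_splits_decades_evenly(self, ref_model):
        samples = ens.sample_enzyme_levels(ref_model, 300, seed=3)
        f = np.concatenate([s.factors for s in samples])  # ~14k draws
        below = np.mean(f < 1.0)
        assert below == pytest.approx(0.5, abs=0.02)
        assert f.min() >= 0.1 and f.max() <= 10.0

    def test_seed_reproducibility(self, ref_model):
        a = ens.sample_enzyme_levels(ref_model, 4, seed=42)
        b = ens.sample_enzyme_levels(ref_model, 4, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.factors, y.factors)

    @pytest.mark.parametrize("lo,hi", [(0.0, 10.0), (2.0, 1.0), (-1.0, 1.0)])
    def test_invalid_bounds(self, ref_model, lo, hi):
        with pytest.raises(ValueError):
            ens.sample_enzyme_levels(ref_model, 2, lo=lo, hi=hi)


class TestEnsembleSteadyStates:
    def test_unit_factors_reproduce_condition_state(self, excess_model, excess_state):
        samples = ens.sample_enzyme_levels(excess_model, 3, lo=1.0, hi=1.0, seed=0)
        result = ens.ensemble_steady_states(excess_model, samples)
        assert result.convergence_rate == 1.0
        for state in result.converged_states():
            assert state.flux("GROWTH") == pytest.approx(
                excess_state.flux("GROWTH"), rel=1e-6
            )

    def test_states_reverify_residual(self, small_ensemble):
        """Every reported steady state passes the residual check when
        re-evaluated from its stored concentrations."""
        model = small_ensemble.model
        for sample, state in zip(
            small_ensemble.converged_samples(), small_ensemble.converged_states()
        ):
            dx = model.rhs(state.concentrations, vmax_scale=sample.factors)
            tol = ABS_TOL + REL_TOL * np.minimum(state.concentrations, 1e3)
            dyn = model.compiled.dynamic
            assert np.all(np.abs(dx[dyn]) <= 10 * tol[dyn])

    def test_growth_coupled_to_uptake(self, small_ensemble):
        """With metabolic regulation, growth rides on glucose uptake."""
        table = small_ensemble.flux_table()
        rho = st.spearmanr(table["GROWTH"], table["PTS"]).statistic
        assert rho > 0.3

    def test_convergence_rate_high(self, small_ensemble):
        assert small_ensemble.convergence_rate > 0.8


class TestStoichiometricModel:
    def test_column_count_matches_kinetic_reactions(self, ref_model):
        smodel = ens.to_stoichiometric(ref_model)
        assert smodel.S.shape[1] == len(ref_model.reactions)

    def test_kinetic_steady_state_satisfies_constraints(self, ref_model, ref_state):
        """Amount fluxes of the kinetic reference state lie in the polytope."""
        smodel = ens.to_stoichiometric(ref_model, flux_cap=1.0)
        F = ref_state.fluxes * ref_model.compiled.reaction_volumes
        assert np.max(np.abs(smodel.S @ F)) < 1e-10
        assert np.all(F <= smodel.upper + 1e-12)
        assert np.all(F >= smodel.lower - 1e-12)

    def test_ensemble_states_satisfy_stoichiometric_constraints(self, small_ensemble):
        """Kinetic solution space is contained in the stoichiometric one."""
        model = small_ensemble.model
        smodel = ens.to_stoichiometric(model, flux_cap=1e6)
        for state in small_ensemble.converged_states()[:25]:
            F = state.fluxes * model.compiled.reaction_volumes
            assert np.max(np.abs(smodel.S @ F)) < 1e-6

    def test_empty_model_rejected(self):
        from colikinetics.model import Compartment, KineticModel, Species

        empty = KineticModel([Compartment("cyt", 1.0, "cytoplasm")],
                             [Species("X", "cyt", 1.0)], [])
        with pytest.raises(ValueError):
            ens.to_stoichiometric(empty)


class TestFluxSampling:
    def test_simplex_moments(self):
        """Branch polytope {f = b1 + b2, 0 <= all <= 1}: the (b1, b2) marginal
        is uniform on the 2-simplex, so E[b_i] = 1/3 and E[f] = 2/3."""
        model, _ = syn.make_branch()
        smodel = ens.to_stoichiometric(model, flux_cap=1.0)
        flux = ens.sample_flux_space(smodel, 10_000, seed=5)
        assert flux["B1"].mean() == pytest.approx(1 / 3, abs=0.02)
        assert flux["B2"].mean() == pytest.approx(1 / 3, abs=0.02)
        assert flux["FEED"].mean() == pytest.approx(2 / 3, abs=0.02)

    def test_samples_satisfy_constraints(self):
        model, _ = syn.make_branch()
        smodel = ens.to_stoichiometric(model, flux_cap=1.0)
        flux = ens.sample_flux_space(smodel, 200, seed=1)
        for i in range(len(flux)):
            assert smodel.check(flux.iloc[i].to_numpy(), tol=1e-9)

    def test_chain_restarts_are_exchangeable(self):
        model, _ = syn.make_branch()
        smodel = ens.to_stoichiometric(model, flux_cap=1.0)
        m1 = ens.sample_flux_space(smodel, 4000, seed=1)["B1"].mean()
        m2 = ens.sample_flux_space(smodel, 4000, seed=2)["B1"].mean()
        assert m1 == pytest.approx(m2, abs=0.03)

    def test_reference_polytope_growth_vs_uptake_uncoupled(self, ref_model):
        """Without kinetics, high uptake mostly coexists with low growth."""
        smodel = ens.to_stoichiometric(ref_model, flux_cap=1.0)
        flux = ens.sample_flux_space(smodel, 1500, seed=9)
        rho = st.spearmanr(flux["GROWTH"], flux["PTS"]).statistic
        assert abs(rho) < 0.5  # no strong coordination from stoichiometry alone


class TestStoichiometricBoundaries:
    def test_branch_triangle_envelope(self):
        model, _ = syn.make_branch()
        smodel = ens.to_stoichiometric(model, flux_cap=1.0)
        bs = ens.stoichiometric_boundaries(smodel, ("FEED", "B1"), [0.0, 0.5, 1.0])
        t = bs.table
        assert t.loc[0, ["y_min", "y_max"]].tolist() == pytest.approx([0.0, 0.0])
        assert t.loc[1, ["y_min", "y_max"]].tolist() == pytest.approx([0.0, 0.5])
        assert t.loc[2, ["y_min", "y_max"]].tolist() == pytest.approx([0.0, 1.0])

    def test_infeasible_grid_point_flagged(self):
        model, _ = syn.make_branch()
        smodel = ens.to_stoichiometric(model, flux_cap=1.0)
        bs = ens.stoichiometric_boundaries(smodel, ("FEED", "B1"), [2.0])
        assert not bs.table.loc[0, "feasible"]

    def test_max_growth_nondecreasing_in_uptake_near_zero(self, ref_model):
        smodel = ens.to_stoichiometric(ref_model, flux_cap=1.0)
        grid = [0.0, 0.01, 0.02, 0.04]
        bs = ens.stoichiometric_boundaries(smodel, ("PTS", "GROWTH"), grid)
        ymax = bs.table["y_max"].to_numpy()
        assert np.all(np.diff(ymax) >= -1e-9)


class TestKineticBoundaries:
    def test_branch_envelope_matches_analytic_extremes(self):
        """Pin the feed flux; the branch-1 share sweeps the analytic interval
        determined by the extreme enzyme ratios (k1 s1)/(k1 s1 + k2 s2)."""
        model, _ = syn.make_branch(feed=1.0, k1=1.0, k2=2.0)
        grid = [0.5, 1.0]
        bs = ens.kinetic_boundaries(model, ("FEED", "B1"), grid, seed=3,
                                    swarm_size=15, iterations=25)
        share_min = 1.0 * 0.1 / (1.0 * 0.1 + 2.0 * 10.0)   # ~0.005
        share_max = 1.0 * 10.0 / (1.0 * 10.0 + 2.0 * 0.1)   # ~0.980
        for row, f in zip(bs.table.itertuples(), grid):
            # the swarm must push far beyond the reference share (1/3) toward
            # both analytic corners, and never leave the feasible interval
            assert row.y_min <= f * 0.05
            assert row.y_max >= f * share_max * 0.9
            assert row.y_min >= f * share_min * 0.5 - 1e-9
            assert row.y_max <= f + 1e-9

    def test_reference_point_inside_unit_envelope(self, excess_model, excess_state):
        """A degenerate single-point grid at the reference uptake brackets the
        reference growth flux."""
        x_ref = excess_state.flux("PTS")
        bs = ens.kinetic_boundaries(excess_model, ("PTS", "GROWTH"), [x_ref],
                                    seed=1, swarm_size=10, iterations=12)
        row = bs.table.iloc[0]
        y_ref = excess_state.flux("GROWTH")
        assert row.y_min <= y_ref + 1e-9
        assert row.y_max >= y_ref - 1e-9


class TestAgainstCobra:
    def test_lp_envelope_matches_cobra_fva(self):
        """Independent oracle: flux variability analysis in cobrapy on the
        branch polytope reproduces the linear-programming envelope."""
        cobra = pytest.importorskip("cobra")

        model, _ = syn.make_branch()
        smodel = ens.to_stoichiometric(model, flux_cap=1.0)

        cm = cobra.Model("branch")
        x = cobra.Metabolite("X")
        feed = cobra.Reaction("FEED"); feed.add_metabolites({x: 1.0})
        b1 = cobra.Reaction("B1"); b1.add_metabolites({x: -1.0})
        b2 = cobra.Reaction("B2"); b2.add_metabolites({x: -1.0})
        for r in (feed, b1, b2):
            r.lower_bound, r.upper_bound = 0.0, 1.0
        cm.add_reactions([feed, b1, b2])

        for pin in (0.3, 0.8):
            ours = ens.stoichiometric_boundaries(smodel, ("FEED", "B1"), [pin]).table
            cm.reactions.FEED.bounds = (pin, pin)
            cm.objective = "B1"
            cm.objective_direction = "max"
            y_max = cm.optimize().objective_value
            cm.objective_direction = "min"
            y_min = cm.optimize().objective_value
            assert ours.loc[0, "y_max"] == pytest.approx(y_max, abs=1e-8)
            assert ours.loc[0, "y_min"] == pytest.approx(y_min, abs=1e-8)
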
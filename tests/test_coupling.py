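"""Systemic variables, coupling statistics and homeostasis."""

import numpy as np
import pandas as pd
import pytest

from colikinetics import coupling as cpl
from colikinetics import ensemble as ens


@pytest.fixture(scope="module")
def var_table(small_ensemble):
    return cpl.systemic_variables(small_ensemble)


class TestSystemicVariables:
    def test_reference_chemostat_growth_column(self, ref_model):
        """A unit-factor ensemble under the chemostat condition reports the
        dilution-rate growth (0.1 1/h) in every row."""
        samples = ens.sample_enzyme_levels(ref_model, 2, lo=1.0, hi=1.0, seed=0)
        result = ens.ensemble_steady_states(ref_model, samples, glucose_mM=None)
        table = cpl.systemic_variables(result)
        assert np.allclose(table["growth_rate"], 0.1, atol=1e-6)

    def test_degenerate_ensemble_rows_identical(self, excess_model):
        samples = ens.sample_enzyme_levels(excess_model, 3, lo=1.0, hi=1.0, seed=0)
        result = ens.ensemble_steady_states(excess_model, samples)
        table = cpl.systemic_variables(result)
        assert (table.nunique() <= 1).all()

    def test_atp_production_is_hand_summed_gross_production(self, excess_model):
        """Gross ATP production equals the sum over ATP-producing reactions of
        stoichiometry-weighted amount fluxes (hand-listed producers)."""
        samples = ens.sample_enzyme_levels(excess_model, 1, lo=1.0, hi=1.0, seed=0)
        result = ens.ensemble_steady_states(excess_model, samples)
        table = cpl.systemic_variables(result)
        state = result.converged_states()[0]
        rvol = excess_model.compiled.reaction_volumes
        rids = list(excess_model.reaction_ids)
        producers = ["GDH", "PYK", "KGDH", "ACK", "ATP_SYN"]
        hand = sum(state.flux(r) * rvol[rids.index(r)] for r in producers)
        hand /= excess_model.compartment("cyt").volume
        assert table.loc[0, "atp_production"] == pytest.approx(hand, rel=1e-9)

    def test_sum_of_fluxes_dominates_uptake(self, var_table):
        assert (var_table["sum_fluxes"] >= var_table["glucose_uptake"] - 1e-12).all()

    def test_yields_are_rate_over_uptake(self, var_table):
        ok = var_table["glucose_uptake"] > 0
        ratio = var_table.loc[ok, "growth_rate"] / var_table.loc[ok, "glucose_uptake"]
        assert np.allclose(ratio, var_table.loc[ok, "biomass_yield"])


class TestEnzymeCost:
    def test_two_reaction_arithmetic(self):
        cost = cpl.enzyme_cost(
            {"A": 2.0, "B": 0.5},
            {"A": 10.0, "B": 4.0},
            {"A": 100, "B": 200},
        )
        assert cost == pytest.approx(2.0 * 10.0 * 100 + 0.5 * 4.0 * 200)

    def test_missing_concentration_uses_average(self):
        cost = cpl.enzyme_cost({"A": 1.0}, {}, {"A": 100})
        assert cost == pytest.approx(18.0 * 100)

    def test_zero_factors_zero_cost(self):
        cost = cpl.enzyme_cost({"A": 0.0, "B": 0.0}, {"A": 1.0}, {"A": 10, "B": 20})
        assert cost == 0.0

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            cpl.enzyme_cost({"A": -1.0}, {}, {"A": 10})

    def test_packaged_table_loads(self):
        table = cpl.load_enzyme_table()
        assert {"reaction", "conc_uM", "aa_count"} <= set(table.columns)
        assert (table["aa_count"] > 0).all()


class TestSpearman:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=200)
        df = pd.DataFrame({"x": x, "y": np.exp(3 * x), "z": -np.sqrt(x)})
        rho = cpl.spearman_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(size=(10_000, 2)), columns=["a", "b"])
        rho = cpl.spearman_matrix(df)
        assert abs(rho.loc["a", "b"]) < 0.05

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            cpl.spearman_matrix(pd.DataFrame({"a": [1, 2, 3]}))

    def test_strong_couplings_in_ensemble(self, var_table):
        """Energy production rates move together across random enzyme states."""
        rho = cpl.spearman_matrix(var_table)
        assert rho.loc["atp_production", "nadh_production"] > 0.5
        assert rho.loc["growth_rate", "glucose_uptake"] > 0.3
        assert rho.loc["o2_uptake", "atp_production"] > 0.5


class TestMutualInformation:
    def test_identical_columns_give_log_bins(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=4000)
        df = pd.DataFrame({"a": x, "b": x})
        mi = cpl.mutual_information_matrix(df, n_bins=8)
        assert mi.loc["a", "b"] == pytest.approx(np.log(8), rel=0.01)
        assert mi.loc["a", "a"] == pytest.approx(np.log(8), rel=0.01)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(size=(2000, 2)), columns=["a", "b"])
        mi = cpl.mutual_information_matrix(df, n_bins=10)
        # plug-in bias is ~ (bins-1)^2 / (2 n)
        assert mi.loc["a", "b"] < 0.05

    def test_symmetry_and_nonnegativity(self, var_table):
        mi = cpl.mutual_information_matrix(var_table.dropna(axis=1))
        arr = mi.to_numpy()
        assert np.allclose(arr, arr.T)
        assert (arr >= -1e-12).all()

    def test_constant_column_zero_with_warning(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.uniform(size=100), "c": np.ones(100)})
        with pytest.warns(UserWarning):
            mi = cpl.mutual_information_matrix(df, n_bins=5)
        assert mi.loc["a", "c"] == 0.0

    def test_strong_rank_couplings_have_high_mi(self, var_table):
        """Pairs flagged by |rho| > 0.85 sit in the top MI quartile."""
        clean = var_table.dropna(axis=1)
        rho = cpl.spearman_matrix(clean)
        mi = cpl.mutual_information_matrix(clean)
        cols = list(clean.columns)
        off = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
        mis = np.array([mi.loc[a, b] for a, b in off])
        threshold = np.quantile(mis, 0.75)
        strong = [(a, b) for a, b in off if abs(rho.loc[a, b]) > 0.85]
        assert strong, "ensemble should contain strongly coupled pairs"
        for a, b in strong:
            assert mi.loc[a, b] >= threshold


class TestHomeostasis:
    def test_single_reference_state(self):
        out = cpl.homeostasis_summary(np.array([47.0]), 47.0)
        assert out["fraction_within_k_fold"] == 1.0

    def test_monotone_in_k(self, var_table, ref_model):
        cyt = [i for i, s in enumerate(ref_model.species)
               if s.compartment == "cyt" and not s.is_boundary]
        ref_total = float(ref_model.initial_concentrations[cyt].sum())
        totals = var_table["total_pool"].to_numpy()
        fracs = [cpl.homeostasis_summary(totals, ref_total, k=k)["fraction_within_k_fold"]
                 for k in (1.5, 2, 3, 5, 10)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_majority_within_three_fold(self, var_table, ref_model):
        """Random enzyme levels leave the total pool within 3-fold of the
        calibrated state for most steady states (metabolite homeostasis)."""
        cyt = [i for i, s in enumerate(ref_model.species)
               if s.compartment == "cyt" and not s.is_boundary]
        ref_total = float(ref_model.initial_concentrations[cyt].sum())
        out = cpl.homeostasis_summary(var_table["total_pool"].to_numpy(), ref_total)
        assert out["fraction_within_k_fold"] > 0.6
        assert out["cumulative_freq"][-1] == 1.0
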
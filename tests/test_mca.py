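"""Metabolic control analysis: theorems, oracles, invariances, robustness."""

import numpy as np
import pandas as pd
import pytest

from colikinetics import mca
from colikinetics import synthetic as syn


@pytest.fixture(scope="module")
def toy_chain():
    return syn.make_toy_chain(2, forms="saturable", feed=1.0,
                              rate_constants=(2.0, 3.0))


@pytest.fixture(scope="module")
def control_matrices(ref_model, ref_state):
    return mca.control_coefficients(ref_model, ref_state)


class TestSummationTheorems:
    def test_reference_flux_rows_sum_to_one(self, control_matrices):
        sums = control_matrices.C_J.sum(axis=1)
        assert float((sums - 1.0).abs().max()) < 0.01

    def test_reference_concentration_rows_sum_to_zero(self, control_matrices):
        sums = control_matrices.C_M.sum(axis=1)
        assert float(sums.abs().max()) < 0.01

    def test_toy_chain_summation(self, toy_chain):
        model, state = toy_chain
        mats = mca.control_coefficients(model)
        assert float((mats.C_J.sum(axis=1) - 1.0).abs().max()) < 0.01
        assert float(mats.C_M.sum(axis=1).abs().max()) < 0.01


class TestFiniteDifferenceOracle:
    def test_matches_brute_force_secant(self, toy_chain):
        """Central log-differences agree with a two-sided 1% secant oracle."""
        model, _ = toy_chain
        mats = mca.control_coefficients(model)
        h = 0.01  # brute-force perturbation: Vmax * (1 +/- 1%)
        for rid in model.reaction_ids:
            up = model.steady_state(vmax_scale={rid: 1 + h})
            dn = model.steady_state(vmax_scale={rid: 1 - h})
            assert up.converged and dn.converged
            for jid in mats.C_J.index:
                brute = (np.log(up.flux(jid)) - np.log(dn.flux(jid))) / (
                    np.log(1 + h) - np.log(1 - h)
                )
                fine = mats.C_J.loc[jid, rid]
                assert fine == pytest.approx(brute, rel=0.02, abs=1e-4)

    def test_richardson_step_halving_consistency(self, toy_chain):
        model, _ = toy_chain
        coarse = mca.control_coefficients(model, perturbation=2e-3)
        fine = mca.control_coefficients(model, perturbation=1e-3)
        diff = (coarse.C_J - fine.C_J).abs().to_numpy().max()
        assert diff < 1e-3


class TestInvariances:
    def test_global_vmax_rescale_leaves_controls_unchanged(self, toy_chain):
        """Scaling every Vmax by a common factor rescales time only."""
        model, _ = toy_chain
        mats1 = mca.control_coefficients(model)
        scaled = model.with_vmax_scale({rid: 2.0 for rid in model.reaction_ids})
        mats2 = mca.control_coefficients(scaled)
        assert np.allclose(mats1.C_J.to_numpy(), mats2.C_J.to_numpy(), atol=1e-6)
        assert np.allclose(mats1.C_M.to_numpy(), mats2.C_M.to_numpy(), atol=1e-6)


class TestOverallControl:
    def test_l2_norm_definition(self):
        cj = pd.DataFrame({"E1": [0.0, 0.0], "E2": [3.0, 4.0], "E3": [0.5, 0.0]},
                          index=["J1", "J2"])
        cm = pd.DataFrame({"E1": [0.0], "E2": [-2.0], "E3": [0.0]}, index=["M1"])
        oc = mca.overall_control(mca.ControlMatrices(C_J=cj, C_M=cm, reference=None))
        assert oc.CJ["E1"] == 0.0          # all-zero column
        assert oc.CJ["E2"] == pytest.approx(5.0)
        assert oc.CJ["E3"] == pytest.approx(0.5)   # single entry -> |c|
        assert oc.CC["E2"] == pytest.approx(2.0)

    def test_environment_dominates_reference_control(self, control_matrices):
        """The glucose supply is the main control point of the network."""
        oc = mca.overall_control(control_matrices)
        assert oc.CJ.idxmax() == "GLC_FEED"
        assert oc.CC.idxmax() == "GLC_FEED"


class TestSummary:
    def test_headline_fractions(self, control_matrices):
        oc = mca.overall_control(control_matrices)
        s = mca.control_summary(oc, control_matrices)
        assert 0.5 < s["flux_enzyme_fraction_within_band"] <= 1.0
        assert s["flux_environment_fraction_above_band"] > 0.5
        assert 0.5 < s["pearson_overall_flux_vs_conc"] <= 1.0
        assert s["pearson_pvalue"] < 1e-6

    def test_identical_vectors_give_pearson_one(self):
        cj = pd.DataFrame(np.random.default_rng(0).uniform(size=(4, 5)))
        mats = mca.ControlMatrices(C_J=cj, C_M=cj.copy(), reference=None)
        oc = mca.overall_control(mats)
        s = mca.control_summary(oc, mats, environment_steps=())
        assert s["pearson_overall_flux_vs_conc"] == pytest.approx(1.0)

    def test_fewer_than_three_steps_error(self):
        cj = pd.DataFrame({"E1": [1.0], "E2": [0.5]}, index=["J1"])
        mats = mca.ControlMatrices(C_J=cj, C_M=cj.copy(), reference=None)
        with pytest.raises(ValueError):
            mca.control_summary(mca.overall_control(mats), mats)


class TestRobustness:
    def test_zero_spread_reproduces_reference(self, toy_chain):
        model, _ = toy_chain
        ref = mca.overall_control(mca.control_coefficients(model))
        rb = mca.control_robustness(model, n_samples=3, spread=0.0, seed=1)
        med = rb["CJ_quantiles"].loc[0.5]
        for rid in model.reaction_ids:
            assert med[rid] == pytest.approx(ref.CJ[rid], rel=1e-6)

    def test_reference_control_ranking_robust_to_parameters(self, ref_model):
        """Glucose supply keeps the largest median overall flux control under
        +/-20% parameter uncertainty (scaled-down sample)."""
        rb = mca.control_robustness(ref_model, n_samples=12, spread=0.2, seed=7)
        med = rb["CJ_quantiles"].loc[0.5]
        assert med.idxmax() == "GLC_FEED"
        iqr = rb["CJ_quantiles"].loc[0.75] - rb["CJ_quantiles"].loc[0.25]
        assert np.all(np.isfinite(iqr.to_numpy()))
        assert rb["n_converged"] >= 6
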
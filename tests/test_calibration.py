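"""Weighted least-squares objective and particle-swarm fitting."""

import numpy as np
import pytest

from colikinetics import synthetic as syn
from colikinetics.calibration import (
    CalibrationDataset,
    DataPoint,
    ParameterSpec,
    fit,
    objective,
    particle_swarm,
    recovery_report,
)


@pytest.fixture(scope="module")
def toy():
    model, state = syn.make_toy_chain(2, forms="saturable", feed=1.0,
                                      rate_constants=(1.0, 2.0))
    free = ["FEED.Vmax", "R1.Vmax", "R2.Vmax"]
    spec = ParameterSpec.for_model(model, free)
    names = list(model.parameter_names)
    truth = {n: model.parameter_vector[names.index(n)] for n in free}
    return model, state, free, spec, truth


class TestObjective:
    def test_perfect_fit_is_zero(self, toy):
        model, state, free, spec, truth = toy
        data = syn.make_calibration_data(model, noise_sigma=0.0, seed=0)
        p = np.array([truth[n] for n in free])
        assert objective(p, model, data, spec) == pytest.approx(0.0, abs=1e-12)

    def test_single_two_sigma_point(self, toy):
        model, state, free, spec, _ = toy
        y = state.flux("R1")
        data = CalibrationDataset(
            [DataPoint("R1", "flux", value=y + 2 * 0.1, sigma=0.1)]
        )
        p = model.parameter_vector[[list(model.parameter_names).index(n) for n in free]]
        assert objective(p, model, data, spec) == pytest.approx(4.0, rel=1e-6)

    def test_chi_squared_expectation(self):
        """At the true parameters the weighted SSE per point concentrates
        near 1 under matched Gaussian noise."""
        model, _ = syn.make_toy_chain(5, feed=1.0,
                                      rate_constants=(1.0, 2.0, 0.8, 1.5, 2.5))
        data = syn.make_calibration_data(
            model, noise_sigma=0.05, times=[0.5, 1.0, 2.0, 4.0, 6.0, 9.0, 14.0, 20.0],
            seed=21,
        )
        assert data.n >= 50
        free = ["FEED.Vmax"]
        spec = ParameterSpec.for_model(model, free)
        p = np.array([1.0])
        chi2_per_point = objective(p, model, data, spec) / data.n
        assert chi2_per_point == pytest.approx(1.0, abs=0.4)

    def test_failure_returns_large_finite_penalty(self, toy):
        model, _, free, spec, _ = toy
        data = syn.make_calibration_data(model, noise_sigma=0.0, seed=0)
        # feed far above consumer capacity: no steady state
        bad = np.array([1000.0, 0.01, 0.01])
        val = objective(bad, model, data, spec)
        assert np.isfinite(val) and val >= 1e30

    def test_nonnegative(self, toy):
        model, _, free, spec, truth = toy
        data = syn.make_calibration_data(model, noise_sigma=0.05, seed=1)
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = np.array([truth[n] for n in free]) * rng.uniform(0.9, 1.1, 3)
            assert objective(p, model, data, spec) >= 0.0


class TestParticleSwarm:
    def test_convex_1d_trace_non_increasing(self):
        f = lambda z: float((z[0] - 0.3) ** 2)
        best, val, trace = particle_swarm(f, np.array([-5.0]), np.array([5.0]),
                                          n_particles=10, iterations=40, seed=0)
        assert best[0] == pytest.approx(0.3, abs=1e-3)
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_degenerate_box_short_circuits(self):
        calls = []
        f = lambda z: calls.append(1) or float(np.sum(z**2))
        best, val, trace = particle_swarm(f, np.array([2.0, 3.0]), np.array([2.0, 3.0]))
        assert np.array_equal(best, [2.0, 3.0])
        assert len(calls) == 1

    def test_respects_bounds(self):
        f = lambda z: float(-np.sum(z))  # pushes to the upper bound
        best, _, _ = particle_swarm(f, np.zeros(3), np.ones(3),
                                    n_particles=15, iterations=30, seed=1)
        assert np.all(best <= 1.0) and np.all(best >= 0.0)
        assert np.all(best > 0.99)


class TestFit:
    def test_zero_noise_recovery_within_5_percent(self, toy):
        model, _, free, spec, truth = toy
        data = syn.make_calibration_data(model, noise_sigma=0.0, seed=3)
        res = fit(model, data, spec, n_particles=30, iterations=80, seed=5)
        rep = recovery_report(truth, res.parameters, spec)
        assert (rep["relative_error"] < 0.05).all()

    def test_seed_reproducibility(self, toy):
        model, _, free, spec, _ = toy
        data = syn.make_calibration_data(model, noise_sigma=0.02, seed=3)
        r1 = fit(model, data, spec, n_particles=10, iterations=15, seed=9)
        r2 = fit(model, data, spec, n_particles=10, iterations=15, seed=9)
        assert r1.trace == r2.trace
        assert r1.parameters == r2.parameters

    def test_degenerate_bounds_return_bounds(self, toy):
        model, _, free, _, truth = toy
        data = syn.make_calibration_data(model, noise_sigma=0.0, seed=3)
        vals = np.array([truth[n] for n in free])
        spec = ParameterSpec(names=free, lower=vals, upper=vals)
        res = fit(model, data, spec, seed=0)
        assert res.parameters == pytest.approx(dict(zip(free, vals)))

    def test_fit_never_leaves_bounds(self, toy):
        model, _, free, spec, _ = toy
        data = syn.make_calibration_data(model, noise_sigma=0.1, seed=4)
        res = fit(model, data, spec, n_particles=12, iterations=20, seed=2)
        for name, lo, hi in zip(spec.names, spec.lower, spec.upper):
            assert lo <= res.parameters[name] <= hi

    def test_noisy_recovery_median_error(self, toy):
        """At 5% noise the recovered parameters stay near the truth."""
        model, _, free, spec, truth = toy
        data = syn.make_calibration_data(model, noise_sigma=0.05, seed=13)
        res = fit(model, data, spec, n_particles=30, iterations=60, seed=6)
        rep = recovery_report(truth, res.parameters, spec)
        assert rep["relative_error"].median() < 0.15


class TestRecoveryReport:
    def test_exact_recovery_zero_errors(self, toy):
        _, _, free, spec, truth = toy
        rep = recovery_report(truth, dict(truth), spec)
        assert (rep["relative_error"] == 0).all()
        assert not rep["at_bound"].any()

    def test_unidentifiable_parameter_is_visible(self, toy):
        """A parameter the data carry no information about (a Km of a step
        observed only through its steady-state flux, which is feed-determined)
        ends far from the truth while identifiable ones are recovered."""
        model, _, _, _, _ = toy
        data = syn.make_calibration_data(
            model, observables=[("X2", "concentration")], noise_sigma=0.0
        )
        free = ["FEED.Vmax", "R1.Km_X1"]
        spec = ParameterSpec.for_model(model, free)
        names = list(model.parameter_names)
        truth = {n: model.parameter_vector[names.index(n)] for n in free}
        res = fit(model, data, spec, n_particles=25, iterations=50, seed=8)
        rep = recovery_report(truth, res.parameters, spec).set_index("parameter")
        assert rep.loc["FEED.Vmax", "relative_error"] < 0.05
        assert rep.loc["R1.Km_X1", "relative_error"] > 0.05
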
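"""Optimizers, Jacobian confidence ranges, Monte-Carlo ensembles."""

import numpy as np
import pytest

from conftest import box1_fit_problem
from mmlsim import estimation as est

T20 = np.linspace(0.1, 2.0, 20)


def linear_problem(y, start=1.0, bounds=(-10.0, 10.0)):
    """One-parameter straight line through the origin, y = p·t."""
    return est.FitProblem(lambda v: {"y": v[0] * T20}, ["p"], {"p": start},
                          {"p": bounds},
                          [est.DataBinding("y", T20, y)])


def bowl_problem(start=(0.0, 0.0)):
    """Two-parameter model whose cost surface is an exact convex bowl."""
    t = np.linspace(0, 1, 21)
    data = [est.DataBinding("y", t, 2 * t + 3 * t * t)]
    return est.FitProblem(lambda v: {"y": v[0] * t + v[1] * t * t},
                          ["p1", "p2"], {"p1": start[0], "p2": start[1]},
                          {"p1": (-10, 10), "p2": (-10, 10)}, data)


class TestOptimizers:
    @pytest.mark.parametrize("method,tol", [
        ("simplex", 1e-4), ("gridsearch", 1e-3), ("sensop", 1e-8),
        ("simanneal", 0.05),
    ])
    def test_convex_bowl_converges(self, method, tol):
        res = est.optimize(bowl_problem(), method, seed=7)
        assert res.params["p1"] == pytest.approx(2.0, abs=tol)
        assert res.params["p2"] == pytest.approx(3.0, abs=tol)

    @pytest.mark.parametrize("method", ["simplex", "sensop"])
    def test_accepted_cost_history_is_non_increasing(self, method):
        res = est.optimize(bowl_problem(), method)
        h = res.history
        assert all(b <= a for a, b in zip(h, h[1:]))

    def test_active_bound_is_respected(self):
        prob = bowl_problem()
        prob.upper = np.array([1.5, 10.0])
        res = est.optimize(prob, "sensop")
        assert res.params["p1"] == pytest.approx(1.5, abs=1e-6)

    def test_failed_solves_become_infinite_cost(self):
        calls = {"n": 0}

        def pred(v):
            calls["n"] += 1
            if v[0] < 0:
                raise RuntimeError("solver blew up")
            return {"y": v[0] * T20}

        prob = est.FitProblem(pred, ["p"], {"p": 1.0}, {"p": (-10, 10)},
                              [est.DataBinding("y", T20, 1.5 * T20)])
        assert prob.cost(np.array([-1.0])) == np.inf
        assert prob.n_failures == 1

    def test_reaction_chain_parameter_recovery(self, box1_plan):
        prob, truth = box1_fit_problem(box1_plan)
        res = est.optimize(prob, "sensop")
        assert res.params["Vhmax"] == pytest.approx(truth["Vhmax"], rel=1e-3)
        assert res.params["Kmh"] == pytest.approx(truth["Kmh"], rel=1e-3)
        assert res.cost < 1e-8

    def test_reaction_chain_bound_clamps_at_limit(self, box1_plan):
        prob, _ = box1_fit_problem(box1_plan)
        prob.upper[0] = 1.5     # Vhmax upper bound below the true 1.84
        res = est.optimize(prob, "sensop")
        assert res.params["Vhmax"] == pytest.approx(1.5, abs=1e-9)


class TestJacobianConfidence:
    def test_straight_line_sd_matches_closed_form(self):
        rng = np.random.default_rng(42)
        sigma, true_p, n = 0.25, 1.5, 2000
        t = np.linspace(0.01, 2.0, n)
        y = true_p * t + sigma * rng.standard_normal(n)
        prob = est.FitProblem(lambda v: {"y": v[0] * t}, ["p"], {"p": 1.0},
                              {"p": (-10, 10)},
                              [est.DataBinding("y", t, y)])
        res = est.optimize(prob, "sensop")
        expected_sd = sigma / np.sqrt(np.sum(t * t))
        assert res.confidence.sd[0] == pytest.approx(expected_sd, rel=0.05)

    def test_collinear_parameters_reported(self):
        # the model uses only the product p1*p2: structurally unidentifiable
        t = np.linspace(0.1, 2, 30)
        rng = np.random.default_rng(0)
        y = 6.0 * t + 0.01 * rng.standard_normal(t.size)  # s^2 > 0
        prob = est.FitProblem(lambda v: {"y": v[0] * v[1] * t},
                              ["p1", "p2"], {"p1": 2.0, "p2": 3.0},
                              {"p1": (0.1, 10), "p2": (0.1, 10)},
                              [est.DataBinding("y", t, y)])
        res = est.optimize(prob, "sensop")
        c = res.confidence
        assert c.condition > 1e10
        assert c.pseudo_inverse
        assert abs(c.correlation[0, 1]) > 0.9

    def test_needs_more_points_than_parameters(self):
        J = np.ones((2, 2))
        with pytest.raises(ValueError):
            est.confidence_from_jacobian(J, 1.0, 2)

    def test_ci_width_shrinks_with_root_data_density(self, box1_plan):
        noise = est.NoiseSpec("proportional_gaussian", 0.05)
        widths = {}
        for n in (40, 80):
            prob, _ = box1_fit_problem(box1_plan, samples=n, noise=noise,
                                       seed=11)
            res = est.optimize(prob, "sensop")
            widths[n] = res.confidence.sd[0]
        ratio = widths[40] / widths[80]
        assert ratio == pytest.approx(np.sqrt(2), abs=0.45)


class TestMonteCarlo:
    def test_zero_noise_reproduces_baseline_exactly(self):
        prob = linear_problem(1.5 * T20)
        base = est.optimize(prob, "sensop", with_confidence=False)
        ens = est.monte_carlo(prob, baseline=base,
                              noise=est.NoiseSpec("proportional_gaussian",
                                                  0.0),
                              reps=10, seed=4)
        assert ens.failures == 0
        assert np.all(ens.estimates == base.vector)
        counts, _ = ens.histograms["p"]
        assert counts.max() == 10          # degenerate histogram

    def test_linear_model_ensemble_matches_closed_form(self):
        sigma, true_p = 0.2, 1.5
        rng = np.random.default_rng(5)
        y = true_p * T20 + sigma * rng.standard_normal(T20.size)
        prob = linear_problem(y)
        base = est.optimize(prob, "sensop")
        ens = est.monte_carlo(prob, baseline=base,
                              noise=est.NoiseSpec("additive_gaussian", sigma),
                              reps=200, seed=99)
        se = sigma / np.sqrt(np.sum(T20 * T20))   # closed-form SE of p-hat
        assert ens.estimates.mean() == pytest.approx(true_p, abs=2 * se)
        assert ens.estimates.std(ddof=1) == pytest.approx(
            base.confidence.sd[0], rel=0.2)

    def test_seed_contract(self):
        y = 1.5 * T20 + 0.1
        prob = linear_problem(y)
        noise = est.NoiseSpec("proportional_gaussian", 0.05)
        a = est.monte_carlo(prob, noise=noise, reps=25, seed=1)
        b = est.monte_carlo(prob, noise=noise, reps=25, seed=1)
        c = est.monte_carlo(prob, noise=noise, reps=25, seed=2)
        assert np.array_equal(a.estimates, b.estimates)
        assert not np.array_equal(a.estimates, c.estimates)

    def test_percentile_interval_covers_at_nominal_rate(self):
        """~95% coverage of the true slope over 400 meta-experiments."""
        sigma, true_p = 0.2, 1.5
        covered = 0
        meta = 400
        for m in range(meta):
            rng = np.random.default_rng(10_000 + m)
            y = true_p * T20 + sigma * rng.standard_normal(T20.size)
            prob = linear_problem(y)
            base = est.optimize(prob, "sensop", with_confidence=False)
            ens = est.monte_carlo(
                prob, baseline=base,
                noise=est.NoiseSpec("additive_gaussian", sigma),
                reps=100, seed=31 * m)
            lo, hi = ens.percentiles["p"]
            covered += (lo <= true_p <= hi)
        assert covered / meta == pytest.approx(0.95, abs=0.04)
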
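"""Loops, sensitivity functions and residual diagnostics."""

import numpy as np
import pytest

from mmlsim import analysis, mml, plan
from mmlsim.analysis import (LoopSpec, residual_diagnostics, run_loops,
                             sensitivity)

DECAY_SRC = """
math decay {
  realDomain t sec; t.min=0; t.max=2; t.delta=0.02;
  real k = 0.6 s^-1;
  real y(t);
  when (t=t.min) { y = 1; }
  y:t = 0 - k*y;
}
"""

IDENTITY_SRC = """
math ident {
  realDomain t sec; t.min=0; t.max=1; t.delta=0.1;
  real P = 2.5;
  real Q(t);
  Q = P;
}
"""


@pytest.fixture(scope="module")
def decay_plan():
    return plan.classify_and_sequence(mml.parse_model(DECAY_SRC))


class TestLoops:
    def test_permeability_family_order_and_peaks(self, box2_plan, cin):
        runs = run_loops(box2_plan,
                         LoopSpec([("PS", [0.0, 1.0, 2.0, 4.0])]),
                         inputs={"Cin": cin})
        assert [r.params["PS"] for r in runs] == [0.0, 1.0, 2.0, 4.0]
        assert all(r.error is None for r in runs)
        peaks = [r.solution["Cout"].max() for r in runs]
        # no extraction at PS=0: the tallest early peak, monotone decline
        assert peaks[0] == max(peaks)
        assert peaks == sorted(peaks, reverse=True)

    def test_degenerate_loop_equals_plain_run(self, box1_plan):
        from mmlsim.ode import solve_model_ode
        runs = run_loops(box1_plan, LoopSpec([("Vhmax", [1.84])]))
        plain = solve_model_ode(box1_plan, params={"Vhmax": 1.84})
        assert np.array_equal(runs[0].solution["U"], plain["U"])

    def test_two_level_family_is_inner_fastest(self, box1_plan):
        runs = run_loops(box1_plan, LoopSpec([
            ("Vhmax", [1.0, 2.0, 3.0]),         # inner
            ("Kmh", [3.0, 4.0, 5.0, 6.0]),      # outer
        ]))
        assert len(runs) == 12
        tags = [(r.params["Kmh"], r.params["Vhmax"]) for r in runs]
        expected = [(k, v) for k in (3.0, 4.0, 5.0, 6.0)
                    for v in (1.0, 2.0, 3.0)]
        assert tags == expected

    def test_family_continues_past_failures(self, box1_plan):
        # a negative Hzero is fine, but a non-finite override breaks the
        # solve; the family records it and carries on
        runs = run_loops(box1_plan, LoopSpec([("Hzero", [np.nan, 46.3])]))
        assert runs[0].error is not None and runs[0].solution is None
        assert runs[1].error is None

    def test_loops_do_not_leak_into_base_run(self, box1_plan):
        from mmlsim.ode import solve_model_ode
        before = solve_model_ode(box1_plan)
        run_loops(box1_plan, LoopSpec([("Vhmax", [0.5, 2.5])]))
        after = solve_model_ode(box1_plan)
        assert np.array_equal(before["U"], after["U"])
        assert np.array_equal(before["H"], after["H"])


class TestSensitivity:
    def test_closed_form_decay_sensitivity(self, decay_plan):
        # y = exp(-k t): normalized sensitivity (dy/y)/(dk/k) = -k t
        res = sensitivity(decay_plan, ["y"], ["k"], delta_rel=1e-3)
        t = analysis.time_grid(res.base)
        expected = -0.6 * t
        assert np.max(np.abs(res.normalized["y"]["k"] - expected)) <= 1e-3

    def test_identity_variable_has_unit_sensitivity(self):
        p = plan.classify_and_sequence(mml.parse_model(IDENTITY_SRC))
        res = sensitivity(p, ["Q"], ["P"], delta_rel=0.01)
        assert np.allclose(res.normalized["Q"]["P"], 1.0, atol=1e-9)

    def test_outflow_conductance_sensitivity_changes_sign(self, box2_plan,
                                                          cin):
        res = sensitivity(box2_plan, ["Cout"], ["PS"], delta_rel=0.01,
                          inputs={"Cin": cin})
        t = analysis.time_grid(res.base)
        s = res.dQdP["Cout"]["PS"]
        cout = analysis.get_series(res.base, "Cout")
        ipk = int(np.argmax(cout))
        # raising the wall conductance lowers the early peak (more solute
        # escapes) and raises the tail (back-flux returns it)
        assert s[ipk] < 0.0
        assert np.all(s[t > 20] > 0.0)

    def test_central_difference_halves_step_dependence(self, box1_plan):
        from conftest import FIT_WINDOW
        kw = dict(base_params=dict(FIT_WINDOW))

        def curve(scheme, d):
            r = sensitivity(box1_plan, ["U"], ["Vhmax"], delta_rel=d,
                            scheme=scheme, **kw)
            return r.dQdP["U"]["Vhmax"]

        fwd = np.max(np.abs(curve("forward", 0.02) - curve("forward", 0.01)))
        cen = np.max(np.abs(curve("central", 0.02) - curve("central", 0.01)))
        assert cen < fwd

    def test_zero_parameter_rejected(self, box2_plan, cin):
        with pytest.raises(ValueError, match="zero"):
            sensitivity(box2_plan, ["Cout"], ["Gisf"], inputs={"Cin": cin})

    def test_normalized_guard_zeroes_negligible_regions(self, box2_plan,
                                                        cin):
        res = sensitivity(box2_plan, ["Cout"], ["PS"], inputs={"Cin": cin})
        cout = np.asarray(analysis.get_series(res.base, "Cout"))
        ns = res.normalized["Cout"]["PS"]
        tiny = np.abs(cout) <= 1e-8 * np.max(np.abs(cout))
        assert np.all(ns[tiny] == 0.0)


class TestResidualDiagnostics:
    def test_perfect_fit(self):
        t = np.linspace(0, 1, 10)
        rep = residual_diagnostics((t, t ** 2), (t, t ** 2))
        assert rep.wssr == 0.0
        assert rep.n_positive == rep.n_negative == 0
        assert rep.n_zero == 10

    def test_alternating_residuals_flag_excess_runs(self):
        # 20 residuals alternating +1/-1: runs = 20; under randomness the
        # expected run count is 1 + 2*10*10/20 = 11 with variance
        # 2*10*10*(200-20)/(20^2*19); the exact z follows
        t = np.arange(20.0)
        y = np.zeros(20)
        r = np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        rep = residual_diagnostics((t, y + r), (t, y))
        assert rep.runs == 20
        assert rep.runs_expected == pytest.approx(11.0)
        var = 2 * 100 * (200 - 20) / (400 * 19)
        assert rep.runs_z == pytest.approx((20 - 11) / np.sqrt(var))
        assert rep.runs_p < 1e-3
        assert rep.systematic_bias       # too MANY runs is also non-random

    def test_single_sign_residuals_flag_bias(self):
        t = np.arange(10.0)
        rep = residual_diagnostics((t, np.ones(10)), (t, np.zeros(10)))
        assert rep.runs == 1
        assert rep.n_negative == 0
        assert rep.systematic_bias

    def test_weighted_ssr_definition(self):
        t = np.arange(4.0)
        data = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.zeros(4)
        w = np.array([1.0, 0.5, 2.0, 0.0])
        rep = residual_diagnostics((t, data), (t, pred), weights=w)
        assert rep.wssr == pytest.approx(np.sum(w * data ** 2))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            residual_diagnostics((np.array([]), np.array([])),
                                 (np.array([0.0, 1.0]), np.array([0.0, 1.0])))
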
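"""PDE engines: stability accounting, advection exactness, conservation,
scheme agreement and refinement behaviour on the two-region exchange model."""

import numpy as np
import pytest

from conftest import bolus_input
from mmlsim.ode import SolveError
from mmlsim.pde import PdeConfig, solve_model_pde, stability_substeps

FCAP_PER_S = 1.0 / 60.0      # 1 ml/(g*min) in ml/(g*s)
VCAP, VISF, L = 0.05, 0.15, 0.1


def outflow_transit_time(sol):
    t = sol.t
    cout, cin = sol["Cout"], sol.boundary["Cin"]
    m1 = np.trapezoid(t * cout, t) / np.trapezoid(cout, t)
    m0 = np.trapezoid(t * cin, t) / np.trapezoid(cin, t)
    return m1 - m0


def total_content(sol, i):
    ccap = np.trapezoid(sol["Ccap"][i], sol.x) / L
    cisf = np.trapezoid(sol["Cisf"][i], sol.x) / L
    return VCAP * ccap + VISF * cisf


class TestStabilitySubsteps:
    def test_unconstrained_single_step(self):
        assert stability_substeps(0.01, 0.0, 0.0, 0.1) == 1

    def test_default_btex_configuration(self):
        # dx = 0.1/30 cm, v = Fcap*L/Vcap = 2 cm/min, D = 1e-5 cm^2/s,
        # dt = 0.1 s, safety 0.8: advective limit needs 2 substeps,
        # diffusive limit is satisfied at 1
        dx = 0.1 / 30
        v = 1.0 * 0.1 / 0.05 / 60.0   # cm/s
        n_adv = int(np.ceil(0.1 * v / (0.8 * dx)))
        n_dif = int(np.ceil(0.1 * 2 * 1e-5 / (0.8 * dx * dx)))
        assert stability_substeps(dx, v, 1e-5, 0.1, 0.8) == max(n_adv, n_dif)
        assert stability_substeps(dx, v, 1e-5, 0.1, 0.8) == 2

    def test_doubling_diffusion_at_the_limit_doubles_substeps(self):
        dx, dt = 0.1, 1.0
        d0 = dx * dx / (2 * dt)  # exactly at the diffusive limit, safety 1
        assert stability_substeps(dx, 0.0, d0, dt, 1.0) == 1
        assert stability_substeps(dx, 0.0, 2 * d0, dt, 1.0) == 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            stability_substeps(0.0, 1.0, 0.0, 0.1)


class TestCoefficientExtraction:
    def test_velocity_and_diffusion_from_equations(self, box2_plan, cin):
        sol = solve_model_pde(box2_plan, inputs={"Cin": cin})
        # velocity Fcap*L/Vcap = 2 cm/min = 1/30 cm/s; Cisf is stagnant
        assert sol.metadata["velocity"]["Ccap"] == pytest.approx(1 / 30)
        assert sol.metadata["velocity"]["Cisf"] == pytest.approx(0.0)
        assert sol.metadata["diffusion"]["Ccap"] == pytest.approx(1e-5)
        assert sol.metadata["diffusion"]["Cisf"] == pytest.approx(1e-6)


class TestAdvection:
    def test_pure_advection_is_exact_for_sliding_scheme(self, box2_plan, cin):
        sol = solve_model_pde(
            box2_plan, params={"PS": 0.0, "Dcap": 0.0, "Disf": 0.0},
            inputs={"Cin": cin}, config=PdeConfig(method="lsfea"))
        # transit Vcap/Fcap = 3 s = 30 reporting steps: outflow equals
        # inflow shifted, with no shape distortion
        shift = 30
        delayed = sol["Cout"][shift:] - sol.boundary["Cin"][:-shift]
        assert np.max(np.abs(delayed)) <= 1e-8

    @pytest.mark.parametrize("method", ["maccormack", "lsfea"])
    def test_mean_transit_time_is_volume_over_flow(self, box2_plan, cin,
                                                   method):
        sol = solve_model_pde(
            box2_plan, params={"PS": 0.0, "Dcap": 1e-8, "Disf": 1e-9},
            inputs={"Cin": cin}, config=PdeConfig(method=method))
        dx_time = (L / 30) / (1 / 30)   # one space step in time units: 0.1 s
        assert outflow_transit_time(sol) == pytest.approx(VCAP / FCAP_PER_S,
                                                          abs=dx_time)

    def test_lsfea_requires_positive_velocity(self, box2_plan, cin):
        with pytest.raises(SolveError, match="velocity|convected"):
            solve_model_pde(box2_plan, params={"Fcap": 0.0},
                            inputs={"Cin": cin},
                            config=PdeConfig(method="lsfea"))


class TestConservation:
    @pytest.mark.parametrize("method", ["maccormack", "lsfea"])
    def test_mass_balance_without_consumption(self, box2_plan, cin, method):
        sol = solve_model_pde(box2_plan, inputs={"Cin": cin},
                              config=PdeConfig(method=method))
        t = sol.t
        inflow = FCAP_PER_S * np.trapezoid(sol.boundary["Cin"], t)
        outflow = FCAP_PER_S * np.trapezoid(sol["Cout"], t)
        residual = total_content(sol, -1)
        assert (outflow + residual) / inflow == pytest.approx(1.0, abs=0.01)

    def test_strong_exchange_and_consumption_destroys_the_bolus(
            self, box2_plan, cin):
        sol = solve_model_pde(box2_plan,
                              params={"PS": 30.0, "Gisf": 30.0},
                              inputs={"Cin": cin})
        t = sol.t
        recovery = (np.trapezoid(sol["Cout"], t)
                    / np.trapezoid(sol.boundary["Cin"], t))
        assert recovery < 0.05

    def test_stagnant_region_stays_empty_without_permeation(self, box2_plan,
                                                            cin):
        sol = solve_model_pde(box2_plan, params={"PS": 0.0, "Gisf": 5.0},
                              inputs={"Cin": cin})
        assert np.max(np.abs(sol["Cisf"])) == 0.0


class TestSchemes:
    def test_two_schemes_agree_on_smooth_input(self, box2_plan, cin):
        mac = solve_model_pde(box2_plan, inputs={"Cin": cin})
        lsf = solve_model_pde(box2_plan, inputs={"Cin": cin},
                              config=PdeConfig(method="lsfea"))
        pk_m, pk_l = mac["Cout"].max(), lsf["Cout"].max()
        assert abs(pk_m - pk_l) / pk_m <= 0.02

    def test_maccormack_self_convergence_is_second_order(self, box2_plan):
        cin = bolus_input()
        sols = {}
        for ngrid in (31, 61, 121):
            sols[ngrid] = solve_model_pde(
                box2_plan, params={"Ngrid": float(ngrid)},
                inputs={"Cin": cin})
        e1 = np.max(np.abs(sols[31]["Cout"] - sols[121]["Cout"]))
        e2 = np.max(np.abs(sols[61]["Cout"] - sols[121]["Cout"]))
        order = np.log2(e1 / e2)
        assert order > 1.2   # ~2 in the asymptotic regime, >1 required

    def test_undershoot_reported_not_clipped(self, box2_plan):
        from mmlsim.funcgen import FuncSpec, make_generator
        sharp = make_generator(FuncSpec(
            "pulse", {"onset": 1.0, "duration": 0.5, "amplitude": 2.0}))
        sol = solve_model_pde(box2_plan, inputs={"Cin": sharp})
        under = sol.metadata["undershoot"]["Ccap"]
        assert under < 0.0                       # sharp front undershoots
        # the tracked bound covers every substep, so it is at least as deep
        # as anything in the reported fields
        assert np.min(sol["Ccap"]) >= under - 1e-12
        assert np.min(sol["Ccap"]) < 0.0
        clipped = solve_model_pde(box2_plan, inputs={"Cin": sharp},
                                  config=PdeConfig(clip_negative=True))
        assert np.min(clipped["Ccap"]) >= 0.0
        # clipping still reports the would-be undershoot
        assert clipped.metadata["undershoot"]["Ccap"] < 0.0
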
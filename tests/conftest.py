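import numpy as np
import pytest
from hypothesis import settings

from mmlsim import funcgen, mml, plan, project

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def box1_source() -> str:
    return project.fixture_source("mm2irrev")


@pytest.fixture(scope="session")
def box2_source() -> str:
    return project.fixture_source("btex20simple")


@pytest.fixture(scope="session")
def box1_model(box1_source) -> mml.ModelDef:
    return mml.parse_model(box1_source)


@pytest.fixture(scope="session")
def box2_model(box2_source) -> mml.ModelDef:
    return mml.parse_model(box2_source)


@pytest.fixture(scope="session")
def box1_plan(box1_model) -> plan.ComputationPlan:
    return plan.classify_and_sequence(box1_model)


@pytest.fixture(scope="session")
def box2_plan(box2_model) -> plan.ComputationPlan:
    return plan.classify_and_sequence(box2_model)


def bolus_input(window=(0.0, 30.0)):
    """The package's canonical smooth inflow bolus: a lognormal density
    (median 3 s, geometric sd exp(0.4), unit area in mM*s) — a realistic
    indicator-dilution injection shape for a 30 s observation window."""
    spec = funcgen.FuncSpec("lognormal",
                            {"median": 3.0, "sigma": 0.4, "area": 1.0},
                            unit="mM", window=window)
    return funcgen.make_generator(spec)


@pytest.fixture(scope="session")
def cin():
    return bolus_input()


@pytest.fixture(scope="session")
def box1_trajectory(box1_plan):
    from mmlsim.ode import SolverConfig, solve_model_ode
    return solve_model_ode(box1_plan, config=SolverConfig(method="dopri5"))


# Box 1's transient is over within ~100 s; fits solve a 300 s window at
# 2 s reporting so parameter estimation stays cheap.
FIT_WINDOW = {"t.max": 300.0, "t.delta": 2.0}


def box1_fit_problem(box1_plan, samples=57, noise=None, seed=0):
    """Synthetic-recovery problem: U(t) sampled over the transient,
    free = {Vhmax, Kmh}, start far from the generating values."""
    from mmlsim import estimation
    ts = np.linspace(10.0, 290.0, samples)
    curve, truth = project.generate_synthetic_dataset(
        box1_plan, "U", ts, noise=noise, seed=seed, params=dict(FIT_WINDOW))
    binding = estimation.DataBinding("U", curve.domain, curve.samples)
    prob = estimation.FitProblem.from_model(
        box1_plan, [binding], ["Vhmax", "Kmh"],
        start={"Vhmax": 1.0, "Kmh": 1.0},
        bounds={"Vhmax": (0.01, 50.0), "Kmh": (0.01, 50.0)},
        fixed=dict(FIT_WINDOW))
    return prob, truth
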
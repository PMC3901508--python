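"""ODE integration engines.

Solver menu:

``euler``, ``rk2``, ``rk4``
    fixed-step explicit Runge-Kutta methods of order 1, 2 and 4; one
    internal step per reporting interval unless ``substeps`` asks for more.
``rk45``
    Runge-Kutta-Fehlberg 4(5) with the classic embedded tableau and
    standard step control (accept when the scaled error estimate is below
    one; next step = 0.9·h·(1/err)^(1/5); steps shortened to land exactly
    on reporting points).
``dopri5``
    Dormand-Prince 5(4) via scipy's RK45.
``auto``
    starts with dopri5; on failure (step-size collapse / rejected
    integration) restarts with the implicit Radau method, which handles
    stiff systems.

Reported values are given at every point of the time-domain grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import mml
from .plan import ComputationPlan, residual_fn, solve_linear_slot

__all__ = ["SolverConfig", "Trajectory", "SolveError", "integrate",
           "solve_model_ode"]

_METHODS = ("euler", "rk2", "rk4", "rk45", "dopri5", "auto")


class SolveError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    method: str = "dopri5"
    rel_tol: float = 1e-7
    abs_tol: float = 1e-9
    min_step: float = 1e-12
    max_step: float = np.inf
    substeps: int = 1          # internal substeps per interval, fixed-step
    stiff_fallback: bool = True
    #: rhs-evaluation budget for the explicit attempt of ``auto``; a stiff
    #: system collapses the step size and burns through this quickly, which
    #: is the trigger for restarting with the implicit fallback
    max_rhs_evals: int = 200_000

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.min_step <= self.max_step:
            raise ValueError("require 0 < min_step <= max_step")


@dataclass
class Trajectory:
    grid: np.ndarray
    values: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]


# ---------------------------------------------------------------------------
# Fixed-step explicit RK steppers
# ---------------------------------------------------------------------------

def _step_euler(f, t, y, h):
    return y + h * f(t, y)


def _step_rk2(f, t, y, h):  # explicit midpoint
    k1 = f(t, y)
    return y + h * f(t + h / 2, y + h / 2 * k1)


def _step_rk4(f, t, y, h):
    k1 = f(t, y)
    k2 = f(t + h / 2, y + h / 2 * k1)
    k3 = f(t + h / 2, y + h / 2 * k2)
    k4 = f(t + h, y + h * k3)
    return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


_FIXED = {"euler": _step_euler, "rk2": _step_rk2, "rk4": _step_rk4}

# Fehlberg 4(5) tableau
_RKF_A = (
    (),
    (1 / 4,),
    (3 / 32, 9 / 32),
    (1932 / 2197, -7200 / 2197, 7296 / 2197),
    (439 / 216, -8, 3680 / 513, -845 / 4104),
    (-8 / 27, 2, -3544 / 2565, 1859 / 4104, -11 / 40),
)
_RKF_C = (0, 1 / 4, 3 / 8, 12 / 13, 1, 1 / 2)
_RKF_B5 = (16 / 135, 0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55)
_RKF_B4 = (25 / 216, 0, 1408 / 2565, 2197 / 4104, -1 / 5, 0)


def _integrate_rkf45(f, y0, grid, cfg: SolverConfig):
    y = np.array(y0, dtype=float)
    out = np.empty((len(grid), y.size))
    out[0] = y
    t = grid[0]
    h = min(cfg.max_step, (grid[-1] - grid[0]) / 100.0)
    nsteps = nrej = 0
    for i in range(1, len(grid)):
        t_target = grid[i]
        while t < t_target - 1e-14 * max(1.0, abs(t_target)):
            h = min(h, t_target - t, cfg.max_step)
            if h < cfg.min_step:
                raise SolveError(f"rk45 step size underflow at t={t:g}")
            ks = []
            for s in range(6):
                ys = y + h * sum(a * k for a, k in zip(_RKF_A[s], ks))
                ks.append(f(t + _RKF_C[s] * h, ys))
            y5 = y + h * sum(b * k for b, k in zip(_RKF_B5, ks))
            y4 = y + h * sum(b * k for b, k in zip(_RKF_B4, ks))
            scale = cfg.abs_tol + cfg.rel_tol * np.maximum(np.abs(y),
                                                           np.abs(y5))
            err = np.sqrt(np.mean(((y5 - y4) / scale) ** 2))
            if err <= 1.0:
                t += h
                y = y5
                nsteps += 1
                fac = 0.9 * (1.0 / err) ** 0.2 if err > 0 else 5.0
            else:
                nrej += 1
                fac = max(0.1, 0.9 * (1.0 / err) ** 0.2)
            h = h * min(5.0, fac)
        out[i] = y
    return out, {"steps": nsteps, "rejected": nrej}


def integrate(rhs, y0, grid, config: SolverConfig | None = None,
              names: list[str] | None = None) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` reporting at every grid point.

    ``grid`` must be strictly increasing and ``y0`` finite.
    """
    config = config or SolverConfig()
    grid = np.asarray(grid, dtype=float)
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite")

    checked_rhs = _check_finite(rhs)
    meta = {"solver": config.method}

    if config.method in _FIXED:
        step = _FIXED[config.method]
        n = max(1, int(config.substeps))
        out = np.empty((len(grid), y0.size))
        out[0] = y = y0
        for i in range(1, len(grid)):
            h = (grid[i] - grid[i - 1]) / n
            t = grid[i - 1]
            for _ in range(n):
                y = step(checked_rhs, t, y, h)
                t += h
            out[i] = y
        meta["steps"] = (len(grid) - 1) * n
    elif config.method == "rk45":
        out, stats = _integrate_rkf45(checked_rhs, y0, grid, config)
        meta.update(stats)
    elif config.method in ("dopri5", "auto"):
        out, meta2 = _solve_scipy(checked_rhs, y0, grid, config)
        meta.update(meta2)
    else:  # pragma: no cover
        raise ValueError(config.method)

    names = names or [f"y{i}" for i in range(y0.size)]
    values = {nm: out[:, i].copy() for i, nm in enumerate(names)}
    return Trajectory(grid=grid, values=values, metadata=meta)


class _BudgetExhausted(Exception):
    pass


def _solve_scipy(rhs, y0, grid, cfg: SolverConfig):
    kw = dict(t_span=(grid[0], grid[-1]), y0=y0, t_eval=grid,
              rtol=cfg.rel_tol, atol=cfg.abs_tol, max_step=cfg.max_step)
    count = [0]

    def metered(t, y):
        count[0] += 1
        if count[0] > cfg.max_rhs_evals:
            raise _BudgetExhausted
        return rhs(t, y)

    failure = None
    try:
        sol = solve_ivp(metered, method="RK45", **kw)
        if not sol.success:
            failure = sol.message
    except _BudgetExhausted:
        failure = (f"explicit solver exceeded {cfg.max_rhs_evals} rhs "
                   "evaluations (step-size collapse)")
    if failure is None:
        return sol.y.T, {"engine": "RK45", "steps": sol.t.size,
                         "rhs_evals": count[0]}
    if cfg.method == "auto" and cfg.stiff_fallback:
        sol = solve_ivp(rhs, method="Radau", **kw)
        if not sol.success:
            raise SolveError(f"Radau fallback failed: {sol.message}")
        return sol.y.T, {"engine": "Radau", "fallback": True,
                         "steps": sol.t.size}
    raise SolveError(f"integration failed: {failure}")


def _check_finite(rhs):
    def wrapped(t, y):
        dy = np.asarray(rhs(t, y), dtype=float)
        if not np.all(np.isfinite(dy)):
            raise SolveError(f"non-finite derivative at t={t:g}")
        return dy
    return wrapped


# ---------------------------------------------------------------------------
# Planned-model solving
# ---------------------------------------------------------------------------

def split_overrides(params: dict | None) -> tuple[dict, dict]:
    """Separate parameter overrides from dotted domain-property overrides
    (``{"PS": 2.0, "t.max": 300.0}``)."""
    pover, props = {}, {}
    for k, v in (params or {}).items():
        (props if "." in k else pover)[k] = v
    return pover, props


def check_param_overrides(plan: ComputationPlan,
                          params: dict | None) -> dict[str, float]:
    """Normalize overrides ``{name: value}`` or ``{name: (value, unit)}``;
    values with a unit are converted to the declared unit (incommensurable
    units are an error).  Dotted keys (domain properties) pass through the
    caller via :func:`split_overrides` and are not accepted here."""
    from . import units as u
    out: dict[str, float] = {}
    if not params:
        return out
    table = u.default_unit_table()
    for name, val in params.items():
        try:
            decl = plan.model.param(name)
        except KeyError:
            raise mml.MmlResolutionError(
                f"override of undeclared parameter {name!r}") from None
        if isinstance(val, tuple):
            value, unit_text = val
            k = u.conversion_factor(u.parse_unit(unit_text, table),
                                    u.parse_unit(decl.unit_text, table))
            out[name] = float(value) * k
        else:
            out[name] = float(val)
    return out


def _base_env(plan: ComputationPlan, pvals: dict[str, float],
              props: dict | None = None) -> dict:
    env = dict(pvals)
    for d in plan.model.domains:
        lo, hi, ct = mml.resolve_domain_grid(plan.model, d, pvals, props)
        env[f"{d.name}.min"] = lo
        env[f"{d.name}.max"] = hi
        env[f"{d.name}.ct"] = float(ct)
        env[f"{d.name}.delta"] = (hi - lo) / (ct - 1)
    return env


class _OdeSystem:
    """Compiled evaluator for the planned ODE system."""

    def __init__(self, plan: ComputationPlan, pvals: dict[str, float],
                 inputs: dict, props: dict | None = None):
        self.plan = plan
        self.tname = plan.time_domain
        self.states = plan.ode_vars
        self.env0 = _base_env(plan, pvals, props)
        self.inputs = inputs
        for name in plan.extern_vars:
            if name not in inputs:
                raise SolveError(f"unbound extern variable {name!r}")
        # compiled forms
        self.alg = []
        for v in plan.algebraic_order:
            c = plan.interior[v]
            lhs, rhs = c.equation.lhs, c.equation.rhs
            if isinstance(lhs, mml.Name) and lhs.id == v:
                self.alg.append((v, mml.compile_expr(rhs), None))
            elif isinstance(rhs, mml.Name) and rhs.id == v:
                self.alg.append((v, mml.compile_expr(lhs), None))
            else:
                self.alg.append((v, None, residual_fn(c.equation)))
        self.derivs = []
        for v in self.states:
            eq = plan.interior[v].equation
            slot = f"{v}:{self.tname}"
            if isinstance(eq.lhs, mml.Deriv) and eq.lhs.key == slot:
                self.derivs.append((v, mml.compile_expr(eq.rhs), None))
            elif isinstance(eq.rhs, mml.Deriv) and eq.rhs.key == slot:
                self.derivs.append((v, mml.compile_expr(eq.lhs), None))
            else:
                self.derivs.append((v, None, residual_fn(eq)))

    def env_at(self, t: float, y: np.ndarray) -> dict:
        env = dict(self.env0)
        env[self.tname] = t
        for name, fn in self.inputs.items():
            env[name] = fn(t)
        for v, yi in zip(self.states, y):
            env[v] = yi
        for v, fexp, fres in self.alg:
            env[v] = (fexp(env) if fexp is not None
                      else solve_linear_slot(fres, env, v))
        return env

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        env = self.env_at(t, y)
        out = np.empty(len(self.states))
        for i, (v, fexp, fres) in enumerate(self.derivs):
            out[i] = (fexp(env) if fexp is not None
                      else solve_linear_slot(fres, env, f"{v}:{self.tname}"))
        return out

    def initial_state(self, t0: float) -> np.ndarray:
        env = dict(self.env0)
        env[self.tname] = t0
        for name, fn in self.inputs.items():
            env[name] = fn(t0)
        y0 = np.empty(len(self.states))
        for i, v in enumerate(self.states):
            f = residual_fn(self.plan.ics[v])
            y0[i] = solve_linear_slot(f, env, v)
            env[v] = y0[i]
        return y0


def solve_model_ode(plan: ComputationPlan,
                    params: dict | None = None,
                    inputs: dict | None = None,
                    config: SolverConfig | None = None) -> Trajectory:
    """Solve a planned ODE model on its time-domain grid.

    ``params`` are overrides (unit-checked against declared units);
    ``inputs`` bind extern variables to callables of time.  The returned
    trajectory carries every declared variable, externs included.
    """
    if plan.pde_vars:
        raise SolveError("model contains PDE variables; use the PDE engine")
    config = config or SolverConfig()
    pover, props = split_overrides(params)
    pvals = plan.param_values(check_param_overrides(plan, pover))
    sys_ = _OdeSystem(plan, pvals, inputs or {}, props)
    tdom = plan.model.domain(plan.time_domain)
    lo, hi, ct = mml.resolve_domain_grid(plan.model, tdom, pvals, props)
    grid = np.linspace(lo, hi, ct)
    y0 = sys_.initial_state(lo)
    traj = integrate(sys_.rhs, y0, grid, config, names=list(sys_.states))
    # recompute algebraic/extern series on the reporting grid
    extra = {v: np.empty(ct) for v, _, _ in sys_.alg}
    for name in plan.extern_vars:
        extra[name] = np.empty(ct)
    if extra:
        for i, t in enumerate(grid):
            y = np.array([traj.values[v][i] for v in sys_.states])
            env = sys_.env_at(t, y)
            for name in extra:
                extra[name][i] = env[name]
        traj.values.update(extra)
    traj.metadata["parameters"] = dict(pvals)
    return traj
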
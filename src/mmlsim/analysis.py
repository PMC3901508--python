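"""Behavioral analysis: parameter loops, finite-difference sensitivity
functions, and residual diagnostics.

Loops run a family of solutions over a Cartesian grid of parameter values
(inner level fastest), tagging each solution with its parameter tuple; a
failed run is recorded and the family continues.  Sensitivity functions
S(t) = dQ/dP are estimated by forward (default) or central differences
with a relative perturbation (default 1%%), and reported both raw and in
the normalized, dimensionless form (dQ/Q)/(dP/P); the normalized curve is
zeroed wherever |Q| is negligible relative to its peak, since the ratio is
meaningless there.  Residual diagnostics compare a data curve against a
model prediction: weighted sum of squared residuals, sign counts, and a
Wald–Wolfowitz runs test for systematic (non-random) misfit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .ode import (SolverConfig, Trajectory, check_param_overrides,
                  solve_model_ode, split_overrides)
from .pde import PdeConfig, SolutionGrid, solve_model_pde
from .plan import ComputationPlan

__all__ = ["LoopSpec", "LoopRun", "run_loops", "SensitivityResult",
           "sensitivity", "ResidualReport", "residual_diagnostics",
           "solve_model", "get_series"]


def solve_model(plan: ComputationPlan, params=None, inputs=None, config=None):
    """Dispatch to the ODE or PDE engine depending on the planned model."""
    if plan.pde_vars:
        cfg = config if isinstance(config, PdeConfig) else PdeConfig()
        return solve_model_pde(plan, params, inputs, cfg)
    cfg = config if isinstance(config, SolverConfig) else SolverConfig()
    return solve_model_ode(plan, params, inputs, cfg)


def get_series(solution, name: str) -> np.ndarray:
    """Time series (or time × space field) of a solved variable."""
    if isinstance(solution, Trajectory):
        return solution.values[name]
    assert isinstance(solution, SolutionGrid)
    if name in solution.values:
        return solution.values[name]
    return solution.boundary[name]


def time_grid(solution) -> np.ndarray:
    return solution.grid if isinstance(solution, Trajectory) else solution.t


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

@dataclass
class LoopSpec:
    """Up to three nested levels of (parameter, values); first level is the
    innermost (fastest-varying) one."""

    levels: list[tuple[str, list[float]]]

    def __post_init__(self):
        if not 1 <= len(self.levels) <= 3:
            raise ValueError("loops support one to three nested levels")
        for name, vals in self.levels:
            if not vals:
                raise ValueError(f"loop over {name!r} has no values")


@dataclass
class LoopRun:
    params: dict[str, float]
    solution: object | None
    error: str | None = None


def run_loops(plan: ComputationPlan, loop: LoopSpec,
              base_params: dict | None = None,
              inputs=None, config=None) -> list[LoopRun]:
    """One solution per Cartesian point of the loop values, inner level
    fastest.  A single run's failure is recorded; the family continues."""
    outer_first = list(reversed(loop.levels))
    grids = [vals for _, vals in outer_first]
    names = [name for name, _ in outer_first]
    runs: list[LoopRun] = []
    idx = [0] * len(grids)

    def tuples():
        # inner level fastest: iterate last axis (= first spec level) fastest
        out = []

        def rec(k, acc):
            if k == len(grids):
                out.append(dict(acc))
                return
            for v in grids[k]:
                acc[names[k]] = float(v)
                rec(k + 1, acc)
        rec(0, {})
        return out

    for tag in tuples():
        p = dict(base_params or {})
        p.update(tag)
        try:
            sol = solve_model(plan, p, inputs, config)
            runs.append(LoopRun(params=tag, solution=sol))
        except Exception as exc:  # family continues past a failed member
            runs.append(LoopRun(params=tag, solution=None, error=str(exc)))
    return runs


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    base: object
    targets: list[str]
    params: list[str]
    delta_rel: float
    scheme: str
    #: target -> param -> unnormalized dQ/dP series
    dQdP: dict[str, dict[str, np.ndarray]]
    #: target -> param -> normalized (dQ/Q)/(dP/P) series
    normalized: dict[str, dict[str, np.ndarray]]
    param_values: dict[str, float] = field(default_factory=dict)


_GUARD = 1e-8


def sensitivity(plan: ComputationPlan, targets: list[str],
                params: list[str], delta_rel: float = 0.01,
                base_params: dict | None = None, inputs=None, config=None,
                scheme: str = "forward",
                guard: float = _GUARD) -> SensitivityResult:
    """Finite-difference sensitivity of target variables to parameters.

    Forward difference by default, S = [Q(P(1+δ)) − Q(P)]/(Pδ); ``central``
    halves the step dependence at the price of a second solve per
    parameter.  A parameter whose base value is zero cannot take a relative
    perturbation and is rejected.
    """
    if delta_rel <= 0:
        raise ValueError("delta_rel must be positive")
    if scheme not in ("forward", "central"):
        raise ValueError(f"unknown difference scheme {scheme!r}")
    base_sol = solve_model(plan, base_params, inputs, config)
    pover, _props = split_overrides(base_params)
    pvals = plan.param_values(check_param_overrides(plan, pover))
    dQdP: dict[str, dict[str, np.ndarray]] = {t: {} for t in targets}
    nS: dict[str, dict[str, np.ndarray]] = {t: {} for t in targets}
    used: dict[str, float] = {}
    for pname in params:
        p0 = pvals[pname]
        if p0 == 0:
            raise ValueError(
                f"parameter {pname!r} is zero; relative perturbation "
                "undefined (use an absolute delta by overriding the base)")
        used[pname] = p0
        dp = p0 * delta_rel
        up = dict(base_params or {})
        up[pname] = p0 + dp
        sol_up = solve_model(plan, up, inputs, config)
        if scheme == "central":
            dn = dict(base_params or {})
            dn[pname] = p0 - dp
            sol_dn = solve_model(plan, dn, inputs, config)
        for tname in targets:
            q0 = np.asarray(get_series(base_sol, tname), dtype=float)
            qup = np.asarray(get_series(sol_up, tname), dtype=float)
            if scheme == "forward":
                s = (qup - q0) / dp
            else:
                qdn = np.asarray(get_series(sol_dn, tname), dtype=float)
                s = (qup - qdn) / (2 * dp)
            dQdP[tname][pname] = s
            qmax = np.max(np.abs(q0)) or 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                ns = s * p0 / q0
            ns = np.where(np.abs(q0) > guard * qmax, ns, 0.0)
            nS[tname][pname] = ns
    return SensitivityResult(base=base_sol, targets=list(targets),
                             params=list(params), delta_rel=delta_rel,
                             scheme=scheme, dQdP=dQdP, normalized=nS,
                             param_values=used)


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ResidualReport:
    abscissae: np.ndarray
    residuals: np.ndarray       # data - model
    weights: np.ndarray
    wssr: float
    n_positive: int
    n_negative: int
    n_zero: int
    runs: int
    runs_expected: float
    runs_z: float
    runs_p: float
    systematic_bias: bool       # single-sign residuals or tiny p-value


def residual_diagnostics(data, prediction, weights=None) -> ResidualReport:
    """Compare a data curve with a model prediction.

    ``data`` is a DataCurve or an (abscissae, values) pair; ``prediction``
    a Trajectory/SolutionGrid variable pair ``(solution, name)`` or an
    (abscissae, values) pair; model values are interpolated linearly onto
    the data abscissae.  The runs test uses the normal approximation to the
    Wald–Wolfowitz run-count distribution over the signs of the non-zero
    residuals (two-sided: both too few runs — systematic misfit — and too
    many — alternation — are flagged).
    """
    if hasattr(data, "domain"):
        td = np.asarray(data.domain, dtype=float)
        yd = np.asarray(data.samples, dtype=float)
        if weights is None and getattr(data, "weights", None) is not None:
            weights = np.asarray(data.weights, dtype=float)
    else:
        td, yd = (np.asarray(a, dtype=float) for a in data)
    if td.size == 0:
        raise ValueError("empty data curve")
    if isinstance(prediction, tuple) and len(prediction) == 2 \
            and isinstance(prediction[1], str):
        sol, name = prediction
        tm = time_grid(sol)
        ym = np.asarray(get_series(sol, name), dtype=float)
    else:
        tm, ym = (np.asarray(a, dtype=float) for a in prediction)
    yhat = np.interp(td, tm, ym)
    r = yd - yhat
    w = np.ones_like(r) if weights is None else np.asarray(weights,
                                                           dtype=float)
    wssr = float(np.sum(w * r * r))
    signs = np.sign(r)
    nz = signs[signs != 0]
    n_pos = int(np.sum(nz > 0))
    n_neg = int(np.sum(nz < 0))
    n_zero = int(np.sum(signs == 0))
    if nz.size:
        runs = int(1 + np.sum(nz[1:] != nz[:-1]))
    else:
        runs = 0
    n = n_pos + n_neg
    if n_pos and n_neg:
        mu = 1 + 2 * n_pos * n_neg / n
        var = (2 * n_pos * n_neg * (2 * n_pos * n_neg - n)
               / (n ** 2 * (n - 1)))
        z = (runs - mu) / np.sqrt(var) if var > 0 else 0.0
        p = float(2 * norm.sf(abs(z)))
    else:
        mu, z = float(max(runs, 1)), 0.0
        p = 1.0 if n == 0 else 0.0  # one-sided residuals: maximal bias
    bias = (n > 0 and (n_pos == 0 or n_neg == 0)) or p < 0.01
    return ResidualReport(
        abscissae=td, residuals=r, weights=w, wssr=wssr,
        n_positive=n_pos, n_negative=n_neg, n_zero=n_zero,
        runs=runs, runs_expected=float(mu), runs_z=float(z), runs_p=p,
        systematic_bias=bool(bias))
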
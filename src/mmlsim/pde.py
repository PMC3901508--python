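"""1-D convection–diffusion–exchange–reaction PDE engines.

Solves planned systems of the blood-tissue-exchange class: for each PDE
variable V(t,x) the interior equation is affine in the spatial-derivative
slots, so it can be written

    dV/dt = -v · dV/dx + D · d²V/dx² + S(V, other variables, t, x)

with a constant velocity v and diffusivity D extracted by probing the
compiled right-hand side, and a pointwise source S carrying exchange and
reaction terms.  Two schemes:

``maccormack``
    predictor (forward-difference advective flux) / corrector
    (backward-difference) average, second-order on smooth profiles;
    diffusion by central differences, source terms pointwise.  Internal
    substeps per reporting step derive from the advective CFL limit
    dt ≤ safety·dx/v and the diffusive limit dt ≤ safety·dx²/(2·D_max).

``lsfea``
    Lagrangian sliding-element operator split: the convective step is
    solved separately and exactly by sliding the convected profile one
    grid cell per internal step (dt = dx/v), then diffusion, exchange and
    reaction are advanced per node over that dt by an RK4 update.
    Reported values are interpolated onto the model's time grid.

Boundary conditions are applied every substep: a total-flux (Robin) inflow
relation is solved for the edge value using a first-order one-sided
derivative, a reflecting edge mirrors its neighbour, a Dirichlet edge is
solved directly.  Negative-concentration undershoot (MacCormack near sharp
fronts) is reported in the metadata, and clipped only on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import mml
from .ode import SolveError, check_param_overrides, _base_env
from .plan import ComputationPlan, residual_fn

__all__ = ["PdeConfig", "SolutionGrid", "stability_substeps",
           "solve_model_pde"]


@dataclass
class PdeConfig:
    method: str = "maccormack"
    cfl_safety: float = 0.8
    clip_negative: bool = False

    def __post_init__(self):
        if self.method not in ("maccormack", "lsfea"):
            raise ValueError(f"unknown PDE method {self.method!r}")
        if not 0 < self.cfl_safety <= 1:
            raise ValueError("cfl_safety must lie in (0, 1]")


@dataclass
class SolutionGrid:
    t: np.ndarray
    x: np.ndarray
    values: dict[str, np.ndarray]           # PDE var -> (nt, nx)
    boundary: dict[str, np.ndarray]         # time-only series, e.g. outflow
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.values:
            return self.values[name]
        return self.boundary[name]


def stability_substeps(dx: float, velocity: float, d_max: float,
                       dt_report: float, cfl_safety: float = 0.8) -> int:
    """Smallest substep count n such that dt_report/n satisfies both the
    advective (dt ≤ s·dx/|v|) and diffusive (dt ≤ s·dx²/(2D)) limits."""
    if dx <= 0 or dt_report <= 0:
        raise ValueError("dx and dt_report must be positive")
    n = 1
    if velocity != 0:
        n = max(n, math.ceil(dt_report * abs(velocity) / (cfl_safety * dx)))
    if d_max > 0:
        n = max(n, math.ceil(dt_report * 2.0 * d_max / (cfl_safety * dx * dx)))
    return n


# ---------------------------------------------------------------------------
# Compiled PDE system
# ---------------------------------------------------------------------------

class _PdeVar:
    def __init__(self, name: str, rhs_fn, velocity: float, diffusion: float):
        self.name = name
        self.rhs_fn = rhs_fn          # full RHS incl. derivative slots
        self.velocity = velocity
        self.diffusion = diffusion
        self.slot1 = None             # f"{name}:{space}"
        self.slot2 = None


class _PdeSystem:
    def __init__(self, plan: ComputationPlan, pvals: dict[str, float],
                 inputs: dict, props: dict | None = None):
        self.plan = plan
        self.tname = plan.time_domain
        self.xname = plan.space_domain
        assert self.xname is not None
        self.env0 = _base_env(plan, pvals, props)
        self.inputs = inputs
        for name in plan.extern_vars:
            if name not in inputs:
                raise SolveError(f"unbound extern variable {name!r}")

        tdom = plan.model.domain(self.tname)
        xdom = plan.model.domain(self.xname)
        tlo, thi, tct = mml.resolve_domain_grid(plan.model, tdom, pvals, props)
        xlo, xhi, xct = mml.resolve_domain_grid(plan.model, xdom, pvals, props)
        self.tgrid = np.linspace(tlo, thi, tct)
        self.xgrid = np.linspace(xlo, xhi, xct)
        self.dx = (xhi - xlo) / (xct - 1)

        self.pde_vars: list[_PdeVar] = []
        for v in plan.pde_vars:
            self.pde_vars.append(self._compile_var(v))
        self.names = [pv.name for pv in self.pde_vars]

    # -- coefficient extraction -------------------------------------------
    def _compile_var(self, name: str) -> _PdeVar:
        eq = self.plan.interior[name].equation
        tslot = f"{name}:{self.tname}"
        s1 = f"{name}:{self.xname}"
        s2 = f"{name}:{self.xname}:{self.xname}"
        if isinstance(eq.lhs, mml.Deriv) and eq.lhs.key == tslot:
            rhs_fn = mml.compile_expr(eq.rhs)
        elif isinstance(eq.rhs, mml.Deriv) and eq.rhs.key == tslot:
            rhs_fn = mml.compile_expr(eq.lhs)
        else:
            res = residual_fn(eq)

            def rhs_fn(env, _res=res, _slot=tslot):
                e = dict(env)
                e[_slot] = 0.0
                f0 = _res(e)
                e[_slot] = 1.0
                return -f0 / (_res(e) - f0)

        def coef(slot: str, state: float) -> float:
            env = dict(self.env0)
            env[self.tname] = float(self.tgrid[0])
            env[self.xname] = float(self.xgrid[0])
            for nm in self.inputs:
                env[nm] = 1.0
            for v in self.plan.pde_vars:
                env[v] = state
                env[f"{v}:{self.xname}"] = 0.0
                env[f"{v}:{self.xname}:{self.xname}"] = 0.0
            f0 = rhs_fn(env)
            env[slot] = 1.0
            return rhs_fn(env) - f0

        vel = -coef(s1, 0.3)
        dif = coef(s2, 0.3)
        if (abs(vel + coef(s1, 1.7)) > 1e-9 * max(1.0, abs(vel))
                or abs(dif - coef(s2, 1.7)) > 1e-9 * max(1.0, abs(dif))):
            raise SolveError(
                f"advective/diffusive coefficients of {name!r} depend on the "
                "state (quasilinear PDEs are not supported)")
        pv = _PdeVar(name, rhs_fn, vel, dif)
        pv.slot1, pv.slot2 = s1, s2
        return pv

    # -- pointwise environment --------------------------------------------
    def env_at(self, t: float, state: dict[str, np.ndarray],
               x=None) -> dict:
        env = dict(self.env0)
        env[self.tname] = t
        env[self.xname] = self.xgrid if x is None else x
        for nm, fn in self.inputs.items():
            env[nm] = fn(t)
        for nm, arr in state.items():
            env[nm] = arr
        return env

    def source(self, t: float, state: dict[str, np.ndarray],
               pv: _PdeVar) -> np.ndarray:
        env = self.env_at(t, state)
        zero = np.zeros_like(self.xgrid)
        for q in self.pde_vars:
            env[q.slot1] = zero
            env[q.slot2] = zero
        out = pv.rhs_fn(env)
        return np.broadcast_to(out, self.xgrid.shape).astype(float)

    # -- boundary application ---------------------------------------------
    # Reflecting (Neumann) edges act as mirror ghosts inside the diffusion
    # operator and never overwrite the edge value — an advected profile must
    # pass through the outflow edge undisturbed.  Robin (total-flux) and
    # Dirichlet conditions determine the edge value and are solved for it
    # each substep using a first-order one-sided derivative.
    def edge_kind(self, var: str, edge: str) -> str:
        bc = self.plan.bcs.get((var, edge))
        if bc is None:
            return "none"
        return "mirror" if bc.form == "neumann" else "set"

    def apply_bcs(self, t: float, state: dict[str, np.ndarray]) -> None:
        dx = self.dx
        for pv in self.pde_vars:
            arr = state[pv.name]
            for edge in ("min", "max"):
                bc = self.plan.bcs.get((pv.name, edge))
                if bc is None or bc.form == "neumann":
                    continue
                i_edge = 0 if edge == "min" else -1
                i_in = 1 if edge == "min" else -2
                sgn = 1.0 if edge == "min" else -1.0
                res = _bc_residual(bc)
                env = self.env_at(t, {nm: state[nm][i_edge]
                                      for nm in state}, x=self.xgrid[i_edge])
                v_in = arr[i_in]

                def f(v_edge):
                    env[pv.name] = v_edge
                    # one-sided first-order derivative toward the interior
                    env[pv.slot1] = sgn * (v_in - v_edge) / dx
                    env[pv.slot2] = 0.0
                    return res(env)

                f0 = f(0.0)
                f1 = f(1.0)
                arr[i_edge] = -f0 / (f1 - f0)

    def laplacian(self, pv: _PdeVar, a: np.ndarray) -> np.ndarray:
        """Central second difference with mirror ghosts on Neumann edges."""
        dx2 = self.dx * self.dx
        out = np.zeros_like(a)
        out[1:-1] = (a[2:] - 2 * a[1:-1] + a[:-2]) / dx2
        if self.edge_kind(pv.name, "min") == "mirror":
            out[0] = 2.0 * (a[1] - a[0]) / dx2
        if self.edge_kind(pv.name, "max") == "mirror":
            out[-1] = 2.0 * (a[-2] - a[-1]) / dx2
        return out

    def aux_values(self, t: float, state: dict[str, np.ndarray]) -> dict:
        if not hasattr(self, "_aux_res"):
            self._aux_res = {name: (edge, residual_fn(eq))
                             for name, (edge, eq)
                             in self.plan.aux_boundary.items()}
        out = {}
        for name, (edge, res) in self._aux_res.items():
            i_edge = 0 if edge == "min" else -1
            env = self.env_at(t, {nm: state[nm][i_edge] for nm in state},
                              x=self.xgrid[i_edge])

            def f(v):
                env[name] = v
                return res(env)

            f0 = f(0.0)
            out[name] = -f0 / (f(1.0) - f0)
        return out

    def initial_state(self) -> dict[str, np.ndarray]:
        t0 = float(self.tgrid[0])
        state: dict[str, np.ndarray] = {}
        for pv in self.pde_vars:
            res = residual_fn(self.plan.ics[pv.name])
            env = self.env_at(t0, state)

            def f(v):
                env[pv.name] = v
                return res(env)

            f0 = f(0.0)
            val = -f0 / (f(1.0) - f0)
            state[pv.name] = np.broadcast_to(
                np.asarray(val, dtype=float), self.xgrid.shape).copy()
        self.apply_bcs(t0, state)
        return state


_BC_CACHE: dict[int, object] = {}


def _bc_residual(bc):
    key = id(bc)
    fn = _BC_CACHE.get(key)
    if fn is None:
        fn = residual_fn(bc.equation)
        _BC_CACHE[key] = fn
    return fn


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def _maccormack_substep(sys_: _PdeSystem, t: float,
                        state: dict[str, np.ndarray], dt: float
                        ) -> dict[str, np.ndarray]:
    dx = sys_.dx

    # predictor: forward differences (one-sided backward at the outflow edge)
    pred: dict[str, np.ndarray] = {}
    for pv in sys_.pde_vars:
        a = state[pv.name]
        fwd = np.zeros_like(a)
        fwd[:-1] = (a[1:] - a[:-1]) / dx
        fwd[-1] = (a[-1] - a[-2]) / dx
        src = sys_.source(t, state, pv)
        pred[pv.name] = a + dt * (-pv.velocity * fwd
                                  + pv.diffusion * sys_.laplacian(pv, a)
                                  + src)
    sys_.apply_bcs(t + dt, pred)
    # corrector: backward differences on the predictor
    new: dict[str, np.ndarray] = {}
    for pv in sys_.pde_vars:
        a0 = state[pv.name]
        ap = pred[pv.name]
        bwd = np.zeros_like(ap)
        bwd[1:] = (ap[1:] - ap[:-1]) / dx
        bwd[0] = (ap[1] - ap[0]) / dx
        srcp = sys_.source(t + dt, pred, pv)
        corr = ap + dt * (-pv.velocity * bwd
                          + pv.diffusion * sys_.laplacian(pv, ap) + srcp)
        new[pv.name] = 0.5 * (a0 + corr)
    sys_.apply_bcs(t + dt, new)
    return new


def _lsfea_process_step(sys_: _PdeSystem, t: float,
                        state: dict[str, np.ndarray], dt: float
                        ) -> dict[str, np.ndarray]:
    """Diffusion + exchange/reaction over dt, RK4 per node (no advection)."""
    dx = sys_.dx

    def rate(tt, st):
        out = {}
        for pv in sys_.pde_vars:
            a = st[pv.name]
            out[pv.name] = (pv.diffusion * sys_.laplacian(pv, a)
                            + sys_.source(tt, st, pv))
        return out

    k1 = rate(t, state)
    s2 = {n: state[n] + 0.5 * dt * k1[n] for n in state}
    k2 = rate(t + 0.5 * dt, s2)
    s3 = {n: state[n] + 0.5 * dt * k2[n] for n in state}
    k3 = rate(t + 0.5 * dt, s3)
    s4 = {n: state[n] + dt * k3[n] for n in state}
    k4 = rate(t + dt, s4)
    return {n: state[n] + dt / 6 * (k1[n] + 2 * k2[n] + 2 * k3[n] + k4[n])
            for n in state}


def solve_model_pde(plan: ComputationPlan,
                    params: dict | None = None,
                    inputs: dict | None = None,
                    config: PdeConfig | None = None) -> SolutionGrid:
    """Solve a planned 1-D PDE model on its time × space grid."""
    if not plan.pde_vars:
        raise SolveError("model contains no PDE variables; use the ODE engine")
    config = config or PdeConfig()
    from .ode import split_overrides
    pover, props = split_overrides(params)
    pvals = plan.param_values(check_param_overrides(plan, pover))
    sys_ = _PdeSystem(plan, pvals, inputs or {}, props)
    tgrid, xgrid = sys_.tgrid, sys_.xgrid
    nt, nx = len(tgrid), len(xgrid)
    dt_report = (tgrid[-1] - tgrid[0]) / (nt - 1)

    values = {pv.name: np.zeros((nt, nx)) for pv in sys_.pde_vars}
    aux_series: dict[str, np.ndarray] = {
        name: np.zeros(nt) for name in plan.aux_boundary}
    extern_series = {name: np.asarray(
        (inputs or {})[name](tgrid), dtype=float) * np.ones(nt)
        for name in plan.extern_vars}

    state = sys_.initial_state()
    undershoot = {pv.name: 0.0 for pv in sys_.pde_vars}

    def record(i, st):
        for pv in sys_.pde_vars:
            values[pv.name][i] = st[pv.name]
        for name, val in sys_.aux_values(tgrid[i], st).items():
            aux_series[name][i] = val

    def track(st):
        for pv in sys_.pde_vars:
            mn = float(np.min(st[pv.name]))
            undershoot[pv.name] = min(undershoot[pv.name], mn)
            if config.clip_negative:
                np.clip(st[pv.name], 0.0, None, out=st[pv.name])

    record(0, state)

    if config.method == "maccormack":
        vmax = max(abs(pv.velocity) for pv in sys_.pde_vars)
        dmax = max(pv.diffusion for pv in sys_.pde_vars)
        nsub = stability_substeps(sys_.dx, vmax, dmax, dt_report,
                                  config.cfl_safety)
        dt = dt_report / nsub
        for i in range(1, nt):
            t = tgrid[i - 1]
            for k in range(nsub):
                state = _maccormack_substep(sys_, t + k * dt, state, dt)
                track(state)
            record(i, state)
        meta_sub = nsub
    else:  # lsfea
        convected = [pv for pv in sys_.pde_vars if abs(pv.velocity) > 0]
        if not convected:
            raise SolveError("lsfea requires a convected variable "
                             "(positive velocity)")
        vels = {round(pv.velocity, 12) for pv in convected}
        if len(vels) > 1:
            raise SolveError("lsfea supports a single convection velocity")
        v = convected[0].velocity
        if v <= 0:
            raise SolveError("lsfea requires positive (min->max) velocity")
        dt_c = sys_.dx / v
        # subcycle the per-node processes if diffusion is too stiff for dt_c
        dmax = max(pv.diffusion for pv in sys_.pde_vars)
        nproc = stability_substeps(sys_.dx, 0.0, dmax, dt_c,
                                   config.cfl_safety)
        t = tgrid[0]
        i_rep = 1
        prev_state = {n: a.copy() for n, a in state.items()}
        t_prev = t
        while i_rep < nt:
            # one slide step
            for pv in convected:
                a = state[pv.name]
                a[1:] = a[:-1]
            sys_.apply_bcs(t + dt_c, state)
            for k in range(nproc):
                state = _lsfea_process_step(sys_, t + k * dt_c / nproc,
                                            state, dt_c / nproc)
            sys_.apply_bcs(t + dt_c, state)
            track(state)
            t_new = t + dt_c
            while i_rep < nt and tgrid[i_rep] <= t_new + 1e-12:
                w = ((tgrid[i_rep] - t_prev) / (t_new - t_prev)
                     if t_new > t_prev else 1.0)
                interp = {n: (1 - w) * prev_state[n] + w * state[n]
                          for n in state}
                record(i_rep, interp)
                i_rep += 1
            prev_state = {n: a.copy() for n, a in state.items()}
            t_prev = t_new
            t = t_new
        meta_sub = nproc

    boundary = dict(aux_series)
    boundary.update(extern_series)
    return SolutionGrid(
        t=tgrid, x=xgrid, values=values, boundary=boundary,
        metadata={
            "method": config.method,
            "substeps": meta_sub,
            "undershoot": undershoot,
            "velocity": {pv.name: pv.velocity for pv in sys_.pde_vars},
            "diffusion": {pv.name: pv.diffusion for pv in sys_.pde_vars},
            "parameters": dict(pvals),
        })
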
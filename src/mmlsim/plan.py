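"""Model compilation: dependency analysis, completeness checking, equation
classification and computation sequencing.

A declarative model is a bag of equations; before anything can be solved the
compiler must decide what each equation computes.  The passes here:

1. unit-balance every equation (via :mod:`mmlsim.units`), keeping the
   annotated form with conversion factors inserted when the model's
   ``unit conversion on`` pragma is set;
2. classify each equation — algebraic, ODE(var), PDE(var), initial
   condition, or boundary condition (Robin total-flux / reflecting Neumann /
   Dirichlet / auxiliary edge definition such as an outflow sampler);
3. verify that every non-extern variable is completely but not overly
   specified (exactly one interior definition; exactly one IC per dynamic
   variable; exactly one BC per spatial edge of a PDE variable);
4. sequence the algebraic assignments topologically (lexicographic
   tie-break, cycles rejected) and expose the dependency graph.

Implicit equations are supported only when linear in a single unknown; the
linear solve is performed numerically at evaluation time by probing the
unknown's slot (the residual is affine in the unknown, so two evaluations
determine it exactly).  Nonlinear-implicit systems are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx

from . import mml, units
from .mml import (Bin, Deriv, Equation, Expr, ModelDef, Name,
                  expr_derivs, expr_symbols)

__all__ = [
    "Diagnostic",
    "PlanError",
    "ClassifiedEq",
    "BoundaryCond",
    "ComputationPlan",
    "build_dependency_graph",
    "classify_and_sequence",
    "validate_model",
    "export_network_graph",
]


@dataclass(frozen=True)
class Diagnostic:
    kind: str       # UNDERSPECIFIED | OVERSPECIFIED | IMBALANCED | UNSUPPORTED
    var: str
    detail: str = ""

    def __str__(self) -> str:
        if self.detail:
            return f"{self.kind}({self.var}: {self.detail})"
        return f"{self.kind}({self.var})"


class PlanError(Exception):
    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        super().__init__("; ".join(str(d) for d in diagnostics))


@dataclass
class ClassifiedEq:
    kind: str               # algebraic | ode | pde
    var: str
    equation: Equation      # annotated (conversion factors inserted)
    explicit: bool = True   # bare variable (or derivative) isolated on one side


@dataclass
class BoundaryCond:
    var: str
    edge: str               # 'min' | 'max'
    form: str               # robin | neumann | dirichlet
    equation: Equation      # annotated


@dataclass
class ComputationPlan:
    model: ModelDef
    symtab: mml.SymbolTable
    unit_env: dict[str, units.UnitExpr]
    time_domain: str
    space_domain: str | None
    interior: dict[str, ClassifiedEq]
    ics: dict[str, Equation]
    bcs: dict[tuple[str, str], BoundaryCond]
    aux_boundary: dict[str, tuple[str, Equation]]  # var -> (edge, annotated eq)
    algebraic_order: list[str]
    order: list[str]
    balance_reports: list[units.BalanceReport]

    @property
    def ode_vars(self) -> list[str]:
        return sorted(v for v, c in self.interior.items() if c.kind == "ode")

    @property
    def pde_vars(self) -> list[str]:
        return sorted(v for v, c in self.interior.items() if c.kind == "pde")

    @property
    def extern_vars(self) -> list[str]:
        return sorted(v.name for v in self.model.variables if v.extern)

    def param_values(self, overrides: dict[str, float] | None = None
                     ) -> dict[str, float]:
        return mml.resolve_param_values(self.model, overrides)

    def serialize(self) -> str:
        """Deterministic JSON summary of the plan (byte-stable for a given
        model source)."""
        doc = {
            "model": self.model.name,
            "time_domain": self.time_domain,
            "space_domain": self.space_domain,
            "interior": {
                v: {"kind": c.kind, "explicit": c.explicit,
                    "equation": _eq_text(c.equation)}
                for v, c in sorted(self.interior.items())
            },
            "initial_conditions": {v: _eq_text(e)
                                   for v, e in sorted(self.ics.items())},
            "boundary_conditions": {
                f"{v}@{edge}": {"form": bc.form, "equation": _eq_text(bc.equation)}
                for (v, edge), bc in sorted(self.bcs.items())
            },
            "auxiliary_boundary": {v: {"edge": edge, "equation": _eq_text(e)}
                                   for v, (edge, e)
                                   in sorted(self.aux_boundary.items())},
            "order": self.order,
            "conversion_factors": [
                {"equation": _eq_text(r.equation),
                 "terms": [{"side": t.side, "term": t.text, "factor": t.factor}
                           for t in r.terms]}
                for r in self.balance_reports
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def _eq_text(eq: Equation) -> str:
    return f"{mml._fmt_expr(eq.lhs)} = {mml._fmt_expr(eq.rhs)}"


# ---------------------------------------------------------------------------
# Linearity probing (shared with engines)
# ---------------------------------------------------------------------------

def residual_fn(eq: Equation):
    """Compiled residual lhs - rhs."""
    return mml.compile_expr(Bin("-", eq.lhs, eq.rhs))


def probe_env(model: ModelDef, rng_values=(0.7, 1.3, 2.1)):
    """Representative numeric environments used for linearity checks."""
    keys = set()
    for eq in model.equations:
        for e in (eq.lhs, eq.rhs):
            keys |= {mml._env_key(x) for x in _leaf_refs(e)}
    envs = []
    for k, base in enumerate(rng_values):
        env = {}
        for j, key in enumerate(sorted(keys)):
            env[key] = base + 0.137 * ((j + k) % 7)
        envs.append(env)
    return envs


def _leaf_refs(e: Expr):
    out = []

    def walk(x):
        if isinstance(x, (Name, mml.Prop, Deriv)):
            out.append(x)
        elif isinstance(x, mml.Un):
            walk(x.operand)
        elif isinstance(x, Bin):
            walk(x.left)
            walk(x.right)
        elif isinstance(x, mml.Call):
            for a in x.args:
                walk(a)

    walk(e)
    return out


def is_linear_in(eq: Equation, slot: str, envs) -> bool:
    """Affine-in-slot test: f(0) - 2 f(1) + f(2) == 0 on probe environments."""
    f = residual_fn(eq)
    for env in envs:
        vals = []
        for s in (0.0, 1.0, 2.0):
            e = dict(env)
            e[slot] = s
            vals.append(f(e))
        scale = max(1.0, *(abs(v) for v in vals))
        if abs(vals[0] - 2 * vals[1] + vals[2]) > 1e-8 * scale:
            return False
    return True


def solve_linear_slot(f, env: dict, slot: str):
    """Solve f == 0 for an unknown entering affinely via env[slot]."""
    e0 = dict(env)
    e0[slot] = 0.0
    f0 = f(e0)
    e0[slot] = 1.0
    f1 = f(e0)
    return -f0 / (f1 - f0)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _bare_var(e: Expr) -> str | None:
    return e.id if isinstance(e, Name) else None


def _classify(model: ModelDef) -> tuple[ComputationPlan | None, list[Diagnostic]]:
    diags: list[Diagnostic] = []
    symtab = mml.resolve_declarations(model)
    table = units.default_unit_table()
    unit_env = units.model_unit_env(model, table)

    # --- unit balance ----------------------------------------------------
    reports = []
    annotated: dict[int, Equation] = {}
    for i, eq in enumerate(model.equations):
        rep = units.check_equation_balance(eq, unit_env,
                                           convert=model.unit_conversion)
        reports.append(rep)
        if not rep.balanced:
            diags.append(Diagnostic("IMBALANCED", _eq_text(eq), rep.message))
        else:
            annotated[i] = rep.annotated if model.unit_conversion else eq
    if diags:
        return None, diags

    var_names = {v.name: v for v in model.variables}
    non_extern = {n for n, v in var_names.items() if not v.extern}

    # --- determine per-variable dynamics from interior equations ---------
    interior_count: dict[str, list[Equation]] = {n: [] for n in var_names}
    interior_kind: dict[str, str] = {}
    time_candidates: dict[str, str] = {}
    space_of: dict[str, str] = {}
    algebraic_eqs: list[Equation] = []

    for i, eq in enumerate(model.equations):
        if eq.guard is not None:
            continue
        aeq = annotated[i]
        derivs = expr_derivs(eq.lhs) + expr_derivs(eq.rhs)
        if not derivs:
            algebraic_eqs.append(aeq)
            continue
        dvars = {d.var for d in derivs}
        if len(dvars) > 1:
            diags.append(Diagnostic(
                "UNSUPPORTED", _eq_text(eq),
                "equation differentiates more than one variable"))
            continue
        var = dvars.pop()
        if var not in non_extern:
            diags.append(Diagnostic("OVERSPECIFIED", var,
                                    "extern variable has a defining equation"))
            continue
        doms = var_names[var].domains
        if len(doms) == 1:
            interior_kind[var] = "ode"
            time_candidates[var] = doms[0]
        else:
            second = {d.domains[0] for d in derivs if d.order == 2}
            first = {d.domains[0] for d in derivs if d.order == 1}
            if len(second) > 1:
                diags.append(Diagnostic(
                    "UNSUPPORTED", var,
                    "second-order derivatives along more than one domain"))
                continue
            if second:
                space = next(iter(second))
                tlike = [d for d in doms if d != space]
                interior_kind[var] = "pde"
                time_candidates[var] = tlike[0]
                space_of[var] = space
            else:
                # first-order only on both domains: convected without
                # diffusion; time axis = the one carrying the outer d/dt,
                # ambiguous unless exactly one domain appears once
                if len(first) == 2:
                    diags.append(Diagnostic(
                        "UNSUPPORTED", var,
                        "cannot identify time-like domain (no second-order "
                        "spatial derivative)"))
                    continue
                tdom = next(iter(first))
                space = [d for d in doms if d != tdom][0]
                interior_kind[var] = "pde"
                time_candidates[var] = tdom
                space_of[var] = space
        interior_count[var].append(aeq)

    if diags:
        return None, diags

    # --- time axis consensus ---------------------------------------------
    axes = set(time_candidates.values())
    if len(axes) > 1:
        return None, [Diagnostic("UNSUPPORTED", ",".join(sorted(axes)),
                                 "more than one time-like integration axis")]
    time_domain = (axes.pop() if axes
                   else (model.domains[0].name if model.domains else ""))
    space_axes = set(space_of.values())
    if len(space_axes) > 1:
        return None, [Diagnostic("UNSUPPORTED", ",".join(sorted(space_axes)),
                                 "more than one spatial domain")]
    space_domain = space_axes.pop() if space_axes else None

    # --- guarded clauses ---------------------------------------------------
    ic_count: dict[str, list[Equation]] = {n: [] for n in var_names}
    bc_count: dict[tuple[str, str], list[BoundaryCond]] = {}
    aux_count: dict[str, list[tuple[str, Equation]]] = {n: [] for n in var_names}

    for i, eq in enumerate(model.equations):
        if eq.guard is None:
            continue
        aeq = annotated[i]
        g = eq.guard
        if g.domain == time_domain:
            if g.edge != "min":
                diags.append(Diagnostic("UNSUPPORTED", g.domain,
                                        "final-time conditions not supported"))
                continue
            var = None
            for cand in (_bare_var(eq.lhs), _bare_var(eq.rhs)):
                if cand in var_names:
                    var = cand
                    break
            if var is None:
                diags.append(Diagnostic("UNSUPPORTED", _eq_text(eq),
                                        "initial condition must isolate a "
                                        "variable"))
                continue
            ic_count[var].append(aeq)
            continue
        if space_domain is not None and g.domain == space_domain:
            derivs = [d for d in expr_derivs(eq.lhs) + expr_derivs(eq.rhs)
                      if d.domains[0] == space_domain]
            if derivs:
                dvars = {d.var for d in derivs}
                if len(dvars) > 1:
                    diags.append(Diagnostic(
                        "UNSUPPORTED", _eq_text(eq),
                        "boundary condition differentiates several variables"))
                    continue
                var = dvars.pop()
                form = _bc_form(aeq, var, space_domain)
                bc_count.setdefault((var, g.edge), []).append(
                    BoundaryCond(var, g.edge, form, aeq))
                continue
            # no spatial derivative: Dirichlet on a PDE var, or an
            # auxiliary edge definition of a lesser-dimensional variable
            lhs_v, rhs_v = _bare_var(eq.lhs), _bare_var(eq.rhs)
            target = None
            for cand in (lhs_v, rhs_v):
                if cand in var_names and space_domain not in \
                        var_names[cand].domains:
                    target = cand
                    break
            if target is not None:
                aux_count[target].append((g.edge, aeq))
                continue
            for cand in (lhs_v, rhs_v):
                if cand in var_names:
                    bc_count.setdefault((cand, g.edge), []).append(
                        BoundaryCond(cand, g.edge, "dirichlet", aeq))
                    target = cand
                    break
            if target is None:
                diags.append(Diagnostic("UNSUPPORTED", _eq_text(eq),
                                        "boundary clause defines no variable"))
            continue
        diags.append(Diagnostic("UNSUPPORTED", g.domain,
                                "guard over a domain with no role"))

    if diags:
        return None, diags

    # --- algebraic equation -> variable assignment ------------------------
    defined = set(interior_kind)
    alg_assign: dict[str, list[Equation]] = {}
    pending = list(algebraic_eqs)
    for _ in range(len(pending) + 1):
        progressed = False
        for eq in list(pending):
            lhs_v, rhs_v = _bare_var(eq.lhs), _bare_var(eq.rhs)
            target = None
            # prefer an isolated variable that still lacks a definition
            for cand in (lhs_v, rhs_v):
                if cand in non_extern and cand not in defined \
                        and cand not in alg_assign:
                    target = cand
                    break
            if target is None:
                # fall back: the single undefined non-extern variable used
                unk = [s for s in sorted(expr_symbols(eq.lhs)
                                         | expr_symbols(eq.rhs))
                       if s in non_extern and s not in defined
                       and s not in alg_assign]
                if len(unk) == 1:
                    target = unk[0]
                elif len(unk) == 0:
                    # everything defined already: attribute to an isolated
                    # side if any (overspecification), else report
                    target = lhs_v if lhs_v in non_extern else rhs_v
                    if target is None:
                        diags.append(Diagnostic(
                            "UNSUPPORTED", _eq_text(eq),
                            "cannot attribute algebraic equation to a "
                            "variable"))
                        pending.remove(eq)
                        progressed = True
                        continue
                else:
                    continue  # wait for other equations to settle
            alg_assign.setdefault(target, []).append(eq)
            pending.remove(eq)
            progressed = True
        if not pending or not progressed:
            break
    for eq in pending:
        diags.append(Diagnostic(
            "UNSUPPORTED", _eq_text(eq),
            "simultaneous implicit algebraic equations are not supported"))
    if diags:
        return None, diags

    # --- completeness accounting ------------------------------------------
    interior: dict[str, ClassifiedEq] = {}
    envs = probe_env(model)
    for name in sorted(non_extern):
        dyn_eqs = interior_count[name]
        alg_eqs = alg_assign.get(name, [])
        aux_eqs = aux_count[name]
        n_def = len(dyn_eqs) + len(alg_eqs) + len(aux_eqs)
        if n_def == 0:
            diags.append(Diagnostic("UNDERSPECIFIED", name,
                                    "no interior defining equation"))
            continue
        if n_def > 1:
            diags.append(Diagnostic("OVERSPECIFIED", name,
                                    "more than one defining equation"))
            continue
        if dyn_eqs:
            kind = interior_kind[name]
            eq = dyn_eqs[0]
            slot = (f"{name}:{time_domain}")
            if not is_linear_in(eq, slot, envs):
                diags.append(Diagnostic(
                    "UNSUPPORTED", name,
                    f"equation nonlinear in {slot} (implicit nonlinear "
                    "equations unsupported)"))
                continue
            explicit = isinstance(eq.lhs, Deriv) or isinstance(eq.rhs, Deriv)
            interior[name] = ClassifiedEq(kind, name, eq, explicit)
            # dynamic variables need exactly one IC
            n_ic = len(ic_count[name])
            if n_ic == 0:
                diags.append(Diagnostic("UNDERSPECIFIED", name,
                                        "missing initial condition"))
            elif n_ic > 1:
                diags.append(Diagnostic("OVERSPECIFIED", name,
                                        "more than one initial condition"))
            if kind == "pde":
                for edge in ("min", "max"):
                    n_bc = len(bc_count.get((name, edge), []))
                    if n_bc == 0:
                        diags.append(Diagnostic(
                            "UNDERSPECIFIED", name,
                            f"missing boundary condition at "
                            f"{space_domain}.{edge}"))
                    elif n_bc > 1:
                        diags.append(Diagnostic(
                            "OVERSPECIFIED", name,
                            f"more than one boundary condition at "
                            f"{space_domain}.{edge}"))
            else:
                for edge in ("min", "max"):
                    if bc_count.get((name, edge)):
                        diags.append(Diagnostic(
                            "OVERSPECIFIED", name,
                            "boundary condition on a non-PDE variable"))
        else:
            # algebraic or auxiliary-boundary definition
            if alg_eqs:
                eq = alg_eqs[0]
                explicit = _bare_var(eq.lhs) == name or _bare_var(eq.rhs) == name
                if not explicit and not is_linear_in(eq, name, envs):
                    diags.append(Diagnostic(
                        "UNSUPPORTED", name,
                        "nonlinear implicit algebraic equation"))
                    continue
                interior[name] = ClassifiedEq("algebraic", name, eq, explicit)
            if ic_count[name]:
                diags.append(Diagnostic(
                    "OVERSPECIFIED", name,
                    "initial condition on a non-differential variable"))
            if any(bc_count.get((name, edge)) for edge in ("min", "max")):
                diags.append(Diagnostic(
                    "OVERSPECIFIED", name,
                    "boundary condition on a non-differential variable"))

    # extern variables must not be defined
    for name, v in var_names.items():
        if not v.extern:
            continue
        if (interior_count[name] or alg_assign.get(name) or aux_count[name]
                or ic_count[name]):
            diags.append(Diagnostic("OVERSPECIFIED", name,
                                    "extern variable has a defining equation"))

    if diags:
        return None, _dedupe(diags)

    ics = {v: eqs[0] for v, eqs in ic_count.items() if eqs}
    bcs = {key: lst[0] for key, lst in bc_count.items()}
    aux = {v: lst[0] for v, lst in aux_count.items() if lst}

    # --- sequencing --------------------------------------------------------
    alg_vars = sorted(v for v, c in interior.items() if c.kind == "algebraic")
    g = nx.DiGraph()
    g.add_nodes_from(alg_vars)
    for v in alg_vars:
        eq = interior[v].equation
        for s in sorted(expr_symbols(eq.lhs) | expr_symbols(eq.rhs)):
            if s != v and s in alg_vars:
                g.add_edge(s, v)
    try:
        alg_order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cyc = sorted({n for c in nx.simple_cycles(g) for n in c})
        return None, [Diagnostic("UNSUPPORTED", ",".join(cyc),
                                 "algebraic dependency cycle")]

    dyn = sorted(v for v, c in interior.items() if c.kind in ("ode", "pde"))
    order = (sorted(p.name for p in model.params) + alg_order + dyn
             + sorted(aux))

    plan = ComputationPlan(
        model=model, symtab=symtab, unit_env=unit_env,
        time_domain=time_domain, space_domain=space_domain,
        interior=interior, ics=ics, bcs=bcs, aux_boundary=aux,
        algebraic_order=alg_order, order=order, balance_reports=reports)
    return plan, []


def _bc_form(eq: Equation, var: str, space: str) -> str:
    """Classify a spatial-edge condition containing d(var)/d(space).

    Recognized linear forms: a·(V − W) + b·V:x = 0 (Robin / total flux),
    V:x = 0 (reflecting Neumann), V = expr (Dirichlet, no derivative —
    handled by the caller).
    """
    f = residual_fn(eq)
    keys = {mml._env_key(x) for x in _leaf_refs(eq.lhs) + _leaf_refs(eq.rhs)}
    base = {k: 0.9 + 0.17 * j for j, k in enumerate(sorted(keys))}
    slot = f"{var}:{space}"

    def coef(target: str) -> float:
        e0 = dict(base)
        e0[target] = 0.0
        f0 = f(e0)
        e0[target] = 1.0
        return f(e0) - f0

    a = coef(var) if var in keys else 0.0
    b = coef(slot)
    if b == 0:
        return "dirichlet"
    return "neumann" if a == 0 else "robin"


def _dedupe(diags: list[Diagnostic]) -> list[Diagnostic]:
    seen, out = set(), []
    for d in diags:
        key = (d.kind, d.var)
        if key not in seen:
            seen.add(key)
            out.append(d)
    return out


def classify_and_sequence(model: ModelDef) -> ComputationPlan:
    """Classify every equation, verify completeness, and sequence the
    computation.  Raises :class:`PlanError` carrying one diagnostic per
    defective variable; returns a deterministic :class:`ComputationPlan`.
    """
    plan, diags = _classify(model)
    if diags:
        raise PlanError(_dedupe(diags))
    assert plan is not None
    return plan


def validate_model(model: ModelDef) -> list[Diagnostic]:
    """Non-raising completeness check; empty list means the plan is valid."""
    try:
        _, diags = _classify(model)
    except mml.MmlError as exc:
        return [Diagnostic("UNSUPPORTED", "model", str(exc))]
    return _dedupe(diags)


# ---------------------------------------------------------------------------
# Dependency graph
# ---------------------------------------------------------------------------

def build_dependency_graph(model: ModelDef,
                           include_params: bool = True) -> nx.DiGraph:
    """Directed graph: edge u → v when u appears in a defining equation of v
    (interior, initial or boundary).  Nodes are variables and domains, plus
    parameters when requested; node attribute ``cls`` distinguishes them.
    """
    mml.resolve_declarations(model)
    g = nx.DiGraph()
    param_names = {p.name for p in model.params}
    for d in model.domains:
        g.add_node(d.name, cls="domain")
    for v in model.variables:
        g.add_node(v.name, cls="extern" if v.extern else "variable")
    if include_params:
        for p in model.params:
            g.add_node(p.name, cls="parameter")

    # defining equations per variable: any equation that isolates or
    # differentiates the variable contributes edges into it
    for eq in model.equations:
        derivs = expr_derivs(eq.lhs) + expr_derivs(eq.rhs)
        targets = {d.var for d in derivs}
        if not targets:
            for side in (eq.lhs, eq.rhs):
                v = _bare_var(side)
                if v is not None and any(vv.name == v and not vv.extern
                                         for vv in model.variables):
                    targets.add(v)
                    break
        for target in targets:
            used = (expr_symbols(eq.lhs) | expr_symbols(eq.rhs)) - {target}
            if eq.guard is not None:
                used.add(eq.guard.domain)
            for u in sorted(used):
                if u == target or u not in g:
                    continue
                if not include_params and u in param_names:
                    continue
                g.add_edge(u, target)
    return g


def export_network_graph(graph: nx.DiGraph, fmt: str = "dot") -> str:
    """Emit the dependency graph as DOT or a JSON twin, with deterministic
    lexicographic node ordering and node classes distinguishable."""
    nodes = sorted(graph.nodes)
    edges = sorted(graph.edges)
    if fmt == "json":
        return json.dumps({
            "nodes": [{"id": n, "class": graph.nodes[n].get("cls", "variable")}
                      for n in nodes],
            "edges": [{"from": u, "to": v} for u, v in edges],
        }, indent=1, sort_keys=True)
    if fmt != "dot":
        raise ValueError(f"unknown graph format {fmt!r}")
    shape = {"variable": "ellipse", "extern": "diamond",
             "parameter": "box", "domain": "plaintext"}
    lines = ["digraph model {"]
    for n in nodes:
        cls = graph.nodes[n].get("cls", "variable")
        lines.append(f'  "{n}" [shape={shape.get(cls, "ellipse")}, '
                     f'class="{cls}"];')
    for u, v in edges:
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
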
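"""Physical-unit algebra and equation unit-balance checking.

A unit is a positive scale factor relative to coherent SI times a vector of
seven rational exponents over the SI base dimensions (length, mass, time,
amount, current, temperature, luminosity).  Commensurable units share a
dimension vector and differ only in scale; the conversion factor between
them is the ratio of scales.

Balance checking walks an equation's expression tree, inferring the unit of
every subexpression.  Additive combination of incommensurable terms is an
IMBALANCED verdict (never an exception).  Under the ``unit conversion on``
pragma, commensurable-but-unequal terms get an explicit numeric conversion
factor inserted into the annotated equation so that every term is expressed
in the unit of the leading (left-hand) term — e.g. a mM/min flux term in a
mM/s rate equation is multiplied by 1/60.  With conversion off such terms
are reported as errors: silent conversion is never performed.

Bare numeric literals are unit-polymorphic ("wild"): ``Ccap = 0`` balances
whatever unit Ccap carries, and ``1 + H/Kmh`` is a dimensionless sum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

from . import mml
from .mml import Bin, Call, Deriv, Equation, Expr, Name, Num, Prop, Un

__all__ = [
    "Dimension",
    "UnitExpr",
    "UnitTable",
    "UnitError",
    "IncommensurableUnitsError",
    "default_unit_table",
    "parse_unit",
    "conversion_factor",
    "BalanceReport",
    "TermReport",
    "check_equation_balance",
    "model_unit_env",
]

_NBASE = 7
_BASE_NAMES = ("length", "mass", "time", "amount", "current",
               "temperature", "luminosity")


class UnitError(ValueError):
    pass


class IncommensurableUnitsError(UnitError):
    pass


@dataclass(frozen=True)
class Dimension:
    """Vector of 7 rational exponents over the SI base dimensions."""

    exponents: tuple[Fraction, ...] = (Fraction(0),) * _NBASE

    def __post_init__(self):
        if len(self.exponents) != _NBASE:
            raise ValueError("dimension vector must have 7 entries")

    def __add__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a + b for a, b in
                               zip(self.exponents, other.exponents)))

    def __sub__(self, other: "Dimension") -> "Dimension":
        return Dimension(tuple(a - b for a, b in
                               zip(self.exponents, other.exponents)))

    def __mul__(self, k) -> "Dimension":
        k = Fraction(k)
        return Dimension(tuple(a * k for a in self.exponents))

    @property
    def dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def __str__(self) -> str:
        if self.dimensionless:
            return "1"
        parts = []
        for name, e in zip(_BASE_NAMES, self.exponents):
            if e != 0:
                parts.append(name if e == 1 else f"{name}^{e}")
        return "·".join(parts)

    @staticmethod
    def base(index: int) -> "Dimension":
        exps = [Fraction(0)] * _NBASE
        exps[index] = Fraction(1)
        return Dimension(tuple(exps))


_LENGTH, _MASS, _TIME, _AMOUNT, _CURRENT, _TEMP, _LUM = range(_NBASE)


@dataclass(frozen=True)
class UnitExpr:
    """scale × dimension: value_in_unit × scale = value_in_coherent_SI."""

    scale: float = 1.0
    dim: Dimension = Dimension()

    def __post_init__(self):
        if not self.scale > 0:
            raise UnitError("unit scale must be positive")

    def __mul__(self, other: "UnitExpr") -> "UnitExpr":
        return UnitExpr(self.scale * other.scale, self.dim + other.dim)

    def __truediv__(self, other: "UnitExpr") -> "UnitExpr":
        return UnitExpr(self.scale / other.scale, self.dim - other.dim)

    def __pow__(self, k) -> "UnitExpr":
        return UnitExpr(self.scale ** float(k), self.dim * Fraction(k))

    @property
    def dimensionless(self) -> bool:
        return self.dim.dimensionless


DIMENSIONLESS = UnitExpr()


def _u(scale: float, **exps) -> UnitExpr:
    vec = [Fraction(0)] * _NBASE
    idx = dict(length=_LENGTH, mass=_MASS, time=_TIME, amount=_AMOUNT,
               current=_CURRENT, temperature=_TEMP, luminosity=_LUM)
    for k, v in exps.items():
        vec[idx[k]] = Fraction(v)
    return UnitExpr(scale, Dimension(tuple(vec)))


#: defined constant, exact by definition of the torr/mmHg
_MMHG_PA = 133.322387415


def default_unit_table() -> "UnitTable":
    """Built-in vocabulary (the practical subset of the nsrunit tables)."""
    t = UnitTable()
    e = t.entries
    e["m"] = _u(1.0, length=1)
    e["cm"] = _u(1e-2, length=1)
    e["mm"] = _u(1e-3, length=1)
    e["um"] = _u(1e-6, length=1)
    e["kg"] = _u(1.0, mass=1)
    e["g"] = _u(1e-3, mass=1)
    e["mg"] = _u(1e-6, mass=1)
    e["s"] = _u(1.0, time=1)
    e["sec"] = _u(1.0, time=1)
    e["min"] = _u(60.0, time=1)
    e["hour"] = _u(3600.0, time=1)
    e["L"] = _u(1e-3, length=3)
    e["ml"] = _u(1e-6, length=3)
    e["ul"] = _u(1e-9, length=3)
    e["mol"] = _u(1.0, amount=1)
    e["mmol"] = _u(1e-3, amount=1)
    e["umol"] = _u(1e-6, amount=1)
    e["M"] = _u(1e3, amount=1, length=-3)     # mol/L
    e["mM"] = _u(1.0, amount=1, length=-3)
    e["uM"] = _u(1e-3, amount=1, length=-3)
    e["Pa"] = _u(1.0, mass=1, length=-1, time=-2)
    e["kPa"] = _u(1e3, mass=1, length=-1, time=-2)
    e["mmHg"] = _u(_MMHG_PA, mass=1, length=-1, time=-2)
    e["A"] = _u(1.0, current=1)
    e["K"] = _u(1.0, temperature=1)
    e["cd"] = _u(1.0, luminosity=1)
    e["dimensionless"] = DIMENSIONLESS
    return t


@dataclass
class UnitTable:
    entries: dict[str, UnitExpr] = field(default_factory=dict)

    def lookup(self, name: str) -> UnitExpr:
        try:
            return self.entries[name]
        except KeyError:
            raise UnitError(f"unknown unit name {name!r}") from None

    def load_definitions(self, text: str) -> None:
        """Extend the table from ``name = expr`` lines (``#`` comments)."""
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise UnitError(f"malformed unit definition line: {raw!r}")
            name, expr = (s.strip() for s in line.split("=", 1))
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
                raise UnitError(f"bad unit name {name!r}")
            self.entries[name] = parse_unit(expr, self)


# ---------------------------------------------------------------------------
# Unit expression parsing:  name [^int], *, /, parentheses, numeric scale
# ---------------------------------------------------------------------------

_UNIT_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|\d+\.?\d*(?:[eE][+-]?\d+)?"
                         r"|\^|\*|/|\(|\)|-)")


def _tokenize_unit(text: str) -> list[str]:
    out, pos = [], 0
    while pos < len(text):
        m = _UNIT_TOKEN.match(text, pos)
        if not m:
            raise UnitError(f"malformed unit expression {text!r} at offset {pos}")
        out.append(m.group(1))
        pos = m.end()
    out.append("")
    return out


def parse_unit(unit_text: str, table: UnitTable | None = None) -> UnitExpr:
    """Parse unit text such as ``ml/(g*min)`` or ``cm^2/sec``."""
    table = table if table is not None else default_unit_table()
    toks = _tokenize_unit(unit_text)
    i = 0

    def peek() -> str:
        return toks[i]

    def take() -> str:
        nonlocal i
        t = toks[i]
        i += 1
        return t

    def factor() -> UnitExpr:
        t = take()
        if t == "(":
            u = group()
            if take() != ")":
                raise UnitError(f"unbalanced parentheses in {unit_text!r}")
        elif re.match(r"[A-Za-z_]", t or " "):
            u = table.lookup(t)
        elif t and t[0].isdigit():
            u = UnitExpr(float(t))
        else:
            raise UnitError(f"malformed unit expression {unit_text!r}")
        if peek() == "^":
            take()
            sign = 1
            if peek() == "-":
                take()
                sign = -1
            p = take()
            if not p or not p[0].isdigit():
                raise UnitError(f"bad exponent in {unit_text!r}")
            u = u ** (sign * Fraction(p))
        return u

    def group() -> UnitExpr:
        u = factor()
        while peek() in ("*", "/"):
            if take() == "*":
                u = u * factor()
            else:
                u = u / factor()
        return u

    u = group()
    if peek() != "":
        raise UnitError(f"trailing content in unit expression {unit_text!r}")
    return u


def conversion_factor(from_unit: UnitExpr, to_unit: UnitExpr) -> float:
    """k such that value_in_from × k = value_in_to."""
    if from_unit.dim != to_unit.dim:
        raise IncommensurableUnitsError(
            f"incommensurable units: {from_unit.dim} vs {to_unit.dim}")
    return from_unit.scale / to_unit.scale


# ---------------------------------------------------------------------------
# Equation balance checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _UV:
    """Unit of a subexpression; wild = bare-literal, adopts any unit."""

    unit: UnitExpr
    wild: bool = False


_WILD = _UV(DIMENSIONLESS, wild=True)


class _Imbalance(Exception):
    def __init__(self, message: str, left: Dimension, right: Dimension):
        super().__init__(message)
        self.message = message
        self.left = left
        self.right = right


@dataclass
class TermReport:
    side: str          # 'lhs' | 'rhs'
    text: str
    dim: Dimension | None   # None for a wild (bare literal) term
    factor: float      # multiplier converting the term into the lhs unit


@dataclass
class BalanceReport:
    equation: Equation
    balanced: bool
    terms: list[TermReport] = field(default_factory=list)
    message: str = ""
    lhs_unit: UnitExpr | None = None
    annotated: Equation | None = None

    @property
    def verdict(self) -> str:
        return "BALANCED" if self.balanced else "IMBALANCED"


_REL_TOL = 1e-12


def _same_scale(a: float, b: float) -> bool:
    return abs(a - b) <= _REL_TOL * max(abs(a), abs(b))


class _Annotator:
    """Infer units bottom-up and insert conversion factors where allowed."""

    def __init__(self, units_of: dict[str, UnitExpr], convert: bool):
        self.units_of = units_of
        self.convert = convert

    def annotate(self, e: Expr) -> tuple[Expr, _UV]:
        if isinstance(e, Num):
            if e.unit_text:
                return e, _UV(parse_unit(e.unit_text))
            return e, _WILD
        if isinstance(e, (Name, Prop, Deriv)):
            key = mml._env_key(e)
            try:
                return e, _UV(self.units_of[key])
            except KeyError:
                raise UnitError(f"no unit known for symbol {key!r}") from None
        if isinstance(e, Un):
            inner, uv = self.annotate(e.operand)
            return Un(e.op, inner), uv
        if isinstance(e, Bin):
            return self._bin(e)
        if isinstance(e, Call):
            return self._call(e)
        raise TypeError(type(e))

    def _bin(self, e: Bin) -> tuple[Expr, _UV]:
        if e.op in ("*", "/"):
            left, lu = self.annotate(e.left)
            right, ru = self.annotate(e.right)
            if lu.wild and ru.wild:
                return Bin(e.op, left, right), _WILD
            unit = (lu.unit * ru.unit) if e.op == "*" else (lu.unit / ru.unit)
            return Bin(e.op, left, right), _UV(unit)
        if e.op in ("+", "-"):
            left, lu = self.annotate(e.left)
            right, ru = self.annotate(e.right)
            if lu.wild and ru.wild:
                return Bin(e.op, left, right), _WILD
            if lu.wild:
                return Bin(e.op, left, right), ru
            if ru.wild:
                return Bin(e.op, left, right), lu
            if lu.unit.dim != ru.unit.dim:
                raise _Imbalance(
                    f"additive terms have incommensurable units "
                    f"({lu.unit.dim} vs {ru.unit.dim})",
                    lu.unit.dim, ru.unit.dim)
            if not _same_scale(lu.unit.scale, ru.unit.scale):
                if not self.convert:
                    raise _Imbalance(
                        "additive terms commensurable but in different units "
                        "and unit conversion is off",
                        lu.unit.dim, ru.unit.dim)
                k = conversion_factor(ru.unit, lu.unit)
                right = Bin("*", Num(k), right)
            return Bin(e.op, left, right), lu
        if e.op == "^":
            return self._pow(e)
        raise ValueError(e.op)

    def _pow(self, e: Bin) -> tuple[Expr, _UV]:
        base, bu = self.annotate(e.left)
        exp, eu = self.annotate(e.right)
        if not (eu.wild or eu.unit.dimensionless):
            raise _Imbalance("exponent must be dimensionless",
                             Dimension(), eu.unit.dim)
        if bu.wild or bu.unit.dimensionless:
            return Bin("^", base, exp), (bu if bu.wild else _UV(DIMENSIONLESS))
        try:
            k = mml.eval_const(e.right, {})
        except (KeyError, TypeError):
            raise _Imbalance(
                "non-constant exponent on a unitful base", bu.unit.dim,
                Dimension()) from None
        frac = Fraction(k).limit_denominator(1000)
        if abs(float(frac) - k) > 1e-12 or frac.denominator != 1:
            raise _Imbalance(
                "non-integer exponent allowed only on dimensionless bases",
                bu.unit.dim, Dimension())
        return Bin("^", base, exp), _UV(bu.unit ** frac)

    def _call(self, e: Call) -> tuple[Expr, _UV]:
        args, uvs = zip(*(self.annotate(a) for a in e.args))
        new = Call(e.fn, tuple(args))
        if e.fn == "abs":
            return new, uvs[0]
        if e.fn == "sqrt":
            uv = uvs[0]
            return new, (uv if uv.wild else _UV(uv.unit ** Fraction(1, 2)))
        # transcendental: argument must be dimensionless
        for uv in uvs:
            if not (uv.wild or uv.unit.dimensionless):
                raise _Imbalance(
                    f"argument of {e.fn}() must be dimensionless",
                    Dimension(), uv.unit.dim)
        return new, _UV(DIMENSIONLESS)


def _additive_terms(e: Expr, sign: int = 1) -> list[tuple[Expr, int]]:
    if isinstance(e, Bin) and e.op in ("+", "-"):
        right_sign = sign if e.op == "+" else -sign
        return (_additive_terms(e.left, sign)
                + _additive_terms(e.right, right_sign))
    if isinstance(e, Un) and e.op == "-":
        return _additive_terms(e.operand, -sign)
    return [(e, sign)]


def check_equation_balance(eq: Equation, units_of: dict[str, UnitExpr],
                           convert: bool = True) -> BalanceReport:
    """Per-term dimensional audit of one equation.

    Returns a verdict, a per-additive-term report (dimension and the factor
    converting the term to the unit of the equation's leading term), and —
    when balanced and ``convert`` is true — an annotated equation with every
    needed conversion factor inserted as an explicit numeric multiplier.
    Imbalance is a verdict, never an exception.
    """
    ann = _Annotator(units_of, convert)
    report = BalanceReport(equation=eq, balanced=True)

    # reference unit: first non-wild top-level term, LHS preferred
    sides = [("lhs", t) for t, _ in _additive_terms(eq.lhs)] + \
            [("rhs", t) for t, _ in _additive_terms(eq.rhs)]
    ref: UnitExpr | None = None
    try:
        term_uvs = []
        for side, term in sides:
            _, uv = ann.annotate(term)
            term_uvs.append((side, term, uv))
            if ref is None and not uv.wild:
                ref = uv.unit
        if ref is None:
            ref = DIMENSIONLESS
        for side, term, uv in term_uvs:
            if uv.wild:
                report.terms.append(TermReport(side, mml._fmt_expr(term),
                                               None, 1.0))
                continue
            if uv.unit.dim != ref.dim:
                report.balanced = False
                report.message = (
                    f"term '{mml._fmt_expr(term)}' has dimension "
                    f"{uv.unit.dim}, expected {ref.dim}")
                report.terms.append(TermReport(side, mml._fmt_expr(term),
                                               uv.unit.dim, float("nan")))
                continue
            report.terms.append(TermReport(side, mml._fmt_expr(term),
                                           uv.unit.dim,
                                           conversion_factor(uv.unit, ref)))
        report.lhs_unit = ref
        if report.balanced:
            new_lhs, lu = ann.annotate(eq.lhs)
            new_rhs, ru = ann.annotate(eq.rhs)
            if not (lu.wild or ru.wild):
                if lu.unit.dim != ru.unit.dim:
                    raise _Imbalance(
                        f"sides have incommensurable units "
                        f"({lu.unit.dim} vs {ru.unit.dim})",
                        lu.unit.dim, ru.unit.dim)
                if not _same_scale(lu.unit.scale, ru.unit.scale):
                    if not convert:
                        raise _Imbalance(
                            "sides commensurable but in different units and "
                            "unit conversion is off", lu.unit.dim, ru.unit.dim)
                    new_rhs = Bin("*", Num(conversion_factor(ru.unit, lu.unit)),
                                  new_rhs)
            report.annotated = Equation(lhs=new_lhs, rhs=new_rhs,
                                        guard=eq.guard, line=eq.line,
                                        col=eq.col)
    except _Imbalance as exc:
        report.balanced = False
        report.message = exc.message
    return report


def model_unit_env(model: mml.ModelDef,
                   table: UnitTable | None = None) -> dict[str, UnitExpr]:
    """Units for every symbol an equation may reference: parameters,
    variables, domains, domain properties, and derivative slots
    (unit(var)/unit(dom)^order)."""
    table = table if table is not None else default_unit_table()
    env: dict[str, UnitExpr] = {}
    dom_units: dict[str, UnitExpr] = {}
    for d in model.domains:
        u = parse_unit(d.unit_text, table)
        dom_units[d.name] = u
        env[d.name] = u
        for prop in ("min", "max", "delta"):
            env[f"{d.name}.{prop}"] = u
        env[f"{d.name}.ct"] = DIMENSIONLESS
    for p in model.params:
        env[p.name] = parse_unit(p.unit_text, table)
    for v in model.variables:
        vu = parse_unit(v.unit_text, table)
        env[v.name] = vu
        for dom in v.domains:
            env[f"{v.name}:{dom}"] = vu / dom_units[dom]
            env[f"{v.name}:{dom}:{dom}"] = vu / (dom_units[dom] ** 2)
    return env
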
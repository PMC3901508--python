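"""Parser and abstract model representation for a declarative modeling language.

The language is a closed subset of MML (Mathematical Modeling Language): a
declarative, unit-annotated equation language for ODE/PDE models.  A model is
a ``math`` block declaring domains (independent variables with uniform grids),
constant parameters, variables on up to two domains, extern inputs, and a set
of equations — interior equations plus ``when``-guarded initial/boundary
clauses.  Equations express mathematical equality, not assignment: the
compiler (see :mod:`mmlsim.plan`) decides what computes what.

This module owns lexing, parsing, the expression AST, two-pass declaration
resolution and a canonical pretty-printer.  Unit semantics live in
:mod:`mmlsim.units`.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field

__all__ = [
    "MmlError",
    "MmlSyntaxError",
    "MmlResolutionError",
    "Expr",
    "Num",
    "Name",
    "Prop",
    "Deriv",
    "Un",
    "Bin",
    "Call",
    "Guard",
    "Equation",
    "DomainDecl",
    "ParamDecl",
    "VarDecl",
    "ModelDef",
    "SymbolTable",
    "parse_model",
    "resolve_declarations",
    "pretty_print",
    "compile_expr",
    "expr_symbols",
]

KEYWORDS = {"real", "realDomain", "extern", "when", "math", "import"}

#: elementary functions admitted in expressions
FUNCTIONS = {"exp", "ln", "log", "sqrt", "abs", "sin", "cos"}


class MmlError(Exception):
    """Base class for all language diagnostics."""

    def __init__(self, message: str, line: int = 0, col: int = 0):
        self.line = line
        self.col = col
        self.message = message
        super().__init__(f"{line}:{col}: error: {message}" if line else message)


class MmlSyntaxError(MmlError):
    pass


class MmlResolutionError(MmlError):
    pass


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

class Expr:
    """Base class for expression nodes (structural equality via dataclasses)."""


@dataclass(frozen=True)
class Num(Expr):
    value: float
    unit_text: str | None = None  # literal unit annotation, declarations only


@dataclass(frozen=True)
class Name(Expr):
    id: str


@dataclass(frozen=True)
class Prop(Expr):
    """Domain property access, e.g. ``t.min`` or ``x.ct``."""

    domain: str
    prop: str  # min | max | delta | ct


@dataclass(frozen=True)
class Deriv(Expr):
    """Derivative ``var:dom`` (order 1) or ``var:dom:dom`` (order 2)."""

    var: str
    domains: tuple[str, ...]

    @property
    def order(self) -> int:
        return len(self.domains)

    @property
    def key(self) -> str:
        return ":".join((self.var,) + self.domains)


@dataclass(frozen=True)
class Un(Expr):
    op: str  # '-'
    operand: Expr


@dataclass(frozen=True)
class Bin(Expr):
    op: str  # + - * / ^
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Call(Expr):
    fn: str
    args: tuple[Expr, ...]


# ---------------------------------------------------------------------------
# Declarations and model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Guard:
    """``when`` anchor: equality of a domain against its min or max."""

    domain: str
    edge: str  # 'min' | 'max'


@dataclass
class Equation:
    lhs: Expr
    rhs: Expr
    guard: Guard | None = None
    line: int = 0
    col: int = 0

    def structural(self) -> tuple:
        return (self.lhs, self.rhs, self.guard)


@dataclass
class DomainDecl:
    """Independent variable with a uniform inclusive grid.

    ``min``/``max``/``delta``/``ct`` are stored as expressions (they may
    reference parameters, e.g. ``x.max = L``) and resolved numerically at
    plan time.  Exactly one of delta / ct determines the grid.
    """

    name: str
    unit_text: str = "dimensionless"
    props: dict[str, Expr] = field(default_factory=dict)
    line: int = 0

    def structural(self) -> tuple:
        return (self.name, self.unit_text, tuple(sorted(self.props.items(),
                                                        key=lambda kv: kv[0])))


@dataclass
class ParamDecl:
    name: str
    value: Expr
    unit_text: str = "dimensionless"
    line: int = 0

    def structural(self) -> tuple:
        return (self.name, self.value, self.unit_text)


@dataclass
class VarDecl:
    name: str
    domains: tuple[str, ...]
    unit_text: str = "dimensionless"
    extern: bool = False
    line: int = 0

    def structural(self) -> tuple:
        return (self.name, self.domains, self.unit_text, self.extern)


@dataclass
class ModelDef:
    name: str
    domains: list[DomainDecl] = field(default_factory=list)
    params: list[ParamDecl] = field(default_factory=list)
    variables: list[VarDecl] = field(default_factory=list)
    equations: list[Equation] = field(default_factory=list)
    unit_conversion: bool = False
    imports: list[str] = field(default_factory=list)

    def domain(self, name: str) -> DomainDecl:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def param(self, name: str) -> ParamDecl:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def variable(self, name: str) -> VarDecl:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def copy(self) -> "ModelDef":
        return copy.deepcopy(self)

    def structural(self) -> tuple:
        """Order-insensitive structural fingerprint used by round-trip tests."""
        return (
            self.name,
            self.unit_conversion,
            tuple(sorted(d.structural() for d in self.domains)),
            tuple(sorted(p.structural() for p in self.params)),
            tuple(sorted(v.structural() for v in self.variables)),
            tuple(sorted((repr(e.structural()) for e in self.equations))),
        )


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<linecomment>//[^\n]*)
  | (?P<blockcomment>/\*.*?\*/)
  | (?P<number>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<punct>[;,=(){}+\-*/^:.])
    """,
    re.VERBOSE | re.DOTALL,
)


@dataclass(frozen=True)
class Token:
    kind: str  # NUMBER | IDENT | punct literal | EOF
    text: str
    line: int
    col: int


def tokenize(source: str) -> list[Token]:
    tokens: list[Token] = []
    pos = 0
    line, col = 1, 1
    n = len(source)
    while pos < n:
        m = _TOKEN_RE.match(source, pos)
        if m is None:
            raise MmlSyntaxError(f"unexpected character {source[pos]!r}", line, col)
        text = m.group(0)
        kind = m.lastgroup
        if kind == "number":
            tokens.append(Token("NUMBER", text, line, col))
        elif kind == "ident":
            tokens.append(Token("IDENT", text, line, col))
        elif kind == "punct":
            tokens.append(Token(text, text, line, col))
        # whitespace and comments are skipped but tracked for position
        nl = text.count("\n")
        if nl:
            line += nl
            col = len(text) - text.rfind("\n")
        else:
            col += len(text)
        pos = m.end()
    tokens.append(Token("EOF", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: list[Token]):
        self.toks = tokens
        self.i = 0
        # property assignments may precede their realDomain declaration;
        # buffered here and attached once the whole block is parsed
        self._prop_assigns: list[tuple[Token, Token, Expr]] = []

    # -- token plumbing ----------------------------------------------------
    def peek(self, ahead: int = 0) -> Token:
        return self.toks[min(self.i + ahead, len(self.toks) - 1)]

    def next(self) -> Token:
        t = self.toks[self.i]
        if t.kind != "EOF":
            self.i += 1
        return t

    def expect(self, kind: str) -> Token:
        t = self.peek()
        if t.kind != kind:
            raise MmlSyntaxError(f"expected {kind!r}, found {t.text!r}", t.line, t.col)
        return self.next()

    def expect_ident(self, word: str | None = None) -> Token:
        t = self.expect("IDENT")
        if word is not None and t.text != word:
            raise MmlSyntaxError(f"expected {word!r}, found {t.text!r}", t.line, t.col)
        return t

    def at_ident(self, word: str) -> bool:
        t = self.peek()
        return t.kind == "IDENT" and t.text == word

    # -- entry -------------------------------------------------------------
    def parse_file(self) -> ModelDef:
        imports: list[str] = []
        unit_conversion = False
        while True:
            t = self.peek()
            if t.kind == "IDENT" and t.text == "import":
                self.next()
                imports.append(self.expect("IDENT").text)
                self.expect(";")
            elif t.kind == "IDENT" and t.text == "unit":
                self.next()
                self.expect_ident("conversion")
                flag = self.expect("IDENT")
                if flag.text not in ("on", "off"):
                    raise MmlSyntaxError("expected 'on' or 'off'", flag.line, flag.col)
                unit_conversion = flag.text == "on"
                self.expect(";")
            elif t.kind == "IDENT" and t.text == "math":
                break
            elif t.kind == "EOF":
                raise MmlSyntaxError("no 'math' block found", t.line, t.col)
            else:
                raise MmlSyntaxError(f"unexpected {t.text!r} before math block",
                                     t.line, t.col)
        self.expect_ident("math")
        name = self.expect("IDENT")
        if name.text in KEYWORDS:
            raise MmlSyntaxError(f"reserved word {name.text!r} used as name",
                                 name.line, name.col)
        model = ModelDef(name=name.text, unit_conversion=unit_conversion,
                         imports=imports)
        self.expect("{")
        while self.peek().kind != "}":
            if self.peek().kind == "EOF":
                t = self.peek()
                raise MmlSyntaxError("unterminated math block", t.line, t.col)
            self.parse_statement(model)
        self.expect("}")
        t = self.peek()
        if t.kind != "EOF":
            raise MmlSyntaxError(f"trailing content {t.text!r} after math block",
                                 t.line, t.col)
        for dom, prop, value in self._prop_assigns:
            target = None
            for d in model.domains:
                if d.name == dom.text:
                    target = d
                    break
            if target is None:
                raise MmlResolutionError(f"undeclared domain {dom.text!r}",
                                         dom.line, dom.col)
            if prop.text in target.props:
                raise MmlResolutionError(
                    f"domain property {dom.text}.{prop.text} assigned twice",
                    dom.line, dom.col)
            target.props[prop.text] = value
        return model

    # -- statements --------------------------------------------------------
    def parse_statement(self, model: ModelDef) -> None:
        t = self.peek()
        if t.kind == "IDENT" and t.text == "realDomain":
            self.parse_domain_decl(model)
        elif t.kind == "IDENT" and t.text in ("real", "extern"):
            self.parse_real_decl(model)
        elif t.kind == "IDENT" and t.text == "when":
            self.parse_when(model)
        elif (t.kind == "IDENT" and self.peek(1).kind == "."
              and self.peek(2).kind == "IDENT"
              and self.peek(2).text in ("min", "max", "delta", "ct")
              and self.peek(3).kind == "="):
            self.parse_prop_assign(model)
        else:
            self.parse_equation(model, guard=None)

    def parse_domain_decl(self, model: ModelDef) -> None:
        self.expect_ident("realDomain")
        name = self.expect("IDENT")
        if name.text in KEYWORDS:
            raise MmlSyntaxError(f"reserved word {name.text!r} used as name",
                                 name.line, name.col)
        unit_text = "dimensionless"
        if self.peek().kind == "IDENT":
            unit_text = self.parse_unit_text()
        self.expect(";")
        model.domains.append(DomainDecl(name=name.text, unit_text=unit_text,
                                        line=name.line))

    def parse_prop_assign(self, model: ModelDef) -> None:
        dom = self.expect("IDENT")
        self.expect(".")
        prop = self.expect("IDENT")
        if prop.text not in ("min", "max", "delta", "ct"):
            raise MmlSyntaxError(f"unknown domain property {prop.text!r}",
                                 prop.line, prop.col)
        self.expect("=")
        value = self.parse_expr(allow_units=True)
        self.expect(";")
        self._prop_assigns.append((dom, prop, value))

    def parse_real_decl(self, model: ModelDef) -> None:
        extern = False
        if self.at_ident("extern"):
            self.next()
            extern = True
        self.expect_ident("real")
        while True:
            self.parse_decl_item(model, extern)
            if self.peek().kind == ",":
                self.next()
                continue
            break
        self.expect(";")

    def parse_decl_item(self, model: ModelDef, extern: bool) -> None:
        name = self.expect("IDENT")
        if name.text in KEYWORDS:
            raise MmlSyntaxError(f"reserved word {name.text!r} used as name",
                                 name.line, name.col)
        if self.peek().kind == "(":
            # variable declaration: name(dom[,dom]) [unit]
            self.next()
            doms = [self.expect("IDENT").text]
            while self.peek().kind == ",":
                self.next()
                doms.append(self.expect("IDENT").text)
            self.expect(")")
            if len(doms) > 2:
                raise MmlSyntaxError(
                    f"variable {name.text!r} declared on {len(doms)} domains "
                    "(at most 2 supported)", name.line, name.col)
            unit_text = "dimensionless"
            if self.peek().kind == "IDENT":
                unit_text = self.parse_unit_text()
            model.variables.append(VarDecl(name=name.text, domains=tuple(doms),
                                           unit_text=unit_text, extern=extern,
                                           line=name.line))
            return
        if extern:
            raise MmlSyntaxError(
                f"extern declaration {name.text!r} must carry a domain list",
                name.line, name.col)
        # parameter declaration: name = value [unit]
        self.expect("=")
        value = self.parse_expr(allow_units=True)
        unit_text = _literal_unit(value) or "dimensionless"
        model.params.append(ParamDecl(name=name.text, value=value,
                                      unit_text=unit_text, line=name.line))

    def parse_when(self, model: ModelDef) -> None:
        kw = self.expect_ident("when")
        self.expect("(")
        dom = self.expect("IDENT")
        self.expect("=")
        owner = self.expect("IDENT")
        self.expect(".")
        edge = self.expect("IDENT")
        if edge.text not in ("min", "max"):
            raise MmlSyntaxError(
                "when-guard must test a domain against its min or max",
                edge.line, edge.col)
        if owner.text != dom.text:
            raise MmlSyntaxError(
                f"when-guard compares {dom.text!r} against property of "
                f"{owner.text!r}", kw.line, kw.col)
        self.expect(")")
        guard = Guard(domain=dom.text, edge=edge.text)
        self.expect("{")
        while self.peek().kind != "}":
            if self.peek().kind == "EOF":
                raise MmlSyntaxError("unterminated when clause", kw.line, kw.col)
            self.parse_equation(model, guard)
        self.expect("}")

    def parse_equation(self, model: ModelDef, guard: Guard | None) -> None:
        t = self.peek()
        lhs = self.parse_expr()
        self.expect("=")
        rhs = self.parse_expr()
        self.expect(";")
        model.equations.append(Equation(lhs=lhs, rhs=rhs, guard=guard,
                                        line=t.line, col=t.col))

    # -- unit text ---------------------------------------------------------
    def parse_unit_text(self) -> str:
        """Consume a maximal unit expression and return its source text."""
        parts: list[str] = [self.expect("IDENT").text]

        def factor_tail():
            if self.peek().kind == "^":
                self.next()
                parts.append("^")
                if self.peek().kind == "-":
                    self.next()
                    parts.append("-")
                parts.append(self.expect("NUMBER").text)

        def factor():
            if self.peek().kind == "(":
                self.next()
                parts.append("(")
                group()
                self.expect(")")
                parts.append(")")
            else:
                parts.append(self.expect("IDENT").text)
                factor_tail()

        def group():
            factor()
            while self.peek().kind in ("*", "/"):
                parts.append(self.next().kind)
                factor()

        factor_tail()
        while self.peek().kind in ("*", "/"):
            op = self.next().kind
            parts.append(op)
            factor()
        return "".join(parts)

    # -- expressions -------------------------------------------------------
    def parse_expr(self, allow_units: bool = False) -> Expr:
        return self.parse_additive(allow_units)

    def parse_additive(self, allow_units: bool = False) -> Expr:
        left = self.parse_multiplicative(allow_units)
        while self.peek().kind in ("+", "-"):
            op = self.next().kind
            right = self.parse_multiplicative(allow_units)
            left = Bin(op, left, right)
        return left

    def parse_multiplicative(self, allow_units: bool = False) -> Expr:
        left = self.parse_unary(allow_units)
        while self.peek().kind in ("*", "/"):
            op = self.next().kind
            right = self.parse_unary(allow_units)
            left = Bin(op, left, right)
        return left

    def parse_unary(self, allow_units: bool = False) -> Expr:
        if self.peek().kind == "-":
            self.next()
            return Un("-", self.parse_unary(allow_units))
        if self.peek().kind == "+":
            self.next()
            return self.parse_unary(allow_units)
        return self.parse_power(allow_units)

    def parse_power(self, allow_units: bool = False) -> Expr:
        base = self.parse_postfix(allow_units)
        if self.peek().kind == "^":
            self.next()
            exponent = self.parse_unary(allow_units)  # right-associative
            return Bin("^", base, exponent)
        return base

    def parse_postfix(self, allow_units: bool) -> Expr:
        t = self.peek()
        if t.kind == "NUMBER":
            self.next()
            unit_text = None
            if allow_units and self.peek().kind == "IDENT":
                unit_text = self.parse_unit_text()
            return Num(float(t.text), unit_text)
        if t.kind == "(":
            self.next()
            inner = self.parse_expr(allow_units)
            self.expect(")")
            return inner
        if t.kind == "IDENT":
            if t.text in KEYWORDS:
                raise MmlSyntaxError(f"reserved word {t.text!r} in expression",
                                     t.line, t.col)
            self.next()
            if t.text in FUNCTIONS and self.peek().kind == "(":
                self.next()
                args = [self.parse_expr()]
                while self.peek().kind == ",":
                    self.next()
                    args.append(self.parse_expr())
                self.expect(")")
                return Call(t.text, tuple(args))
            if self.peek().kind == ".":
                self.next()
                prop = self.expect("IDENT")
                if prop.text not in ("min", "max", "delta", "ct"):
                    raise MmlSyntaxError(
                        f"unknown domain property {prop.text!r}",
                        prop.line, prop.col)
                return Prop(t.text, prop.text)
            if self.peek().kind == ":":
                doms = []
                while self.peek().kind == ":":
                    self.next()
                    doms.append(self.expect("IDENT").text)
                if len(doms) > 2:
                    raise MmlSyntaxError(
                        "derivatives above second order are not supported",
                        t.line, t.col)
                return Deriv(t.text, tuple(doms))
            return Name(t.text)
        raise MmlSyntaxError(f"unexpected {t.text!r} in expression", t.line, t.col)


def _literal_unit(expr: Expr) -> str | None:
    """Unit annotation of the leading numeric literal of an initializer."""
    if isinstance(expr, Num):
        return expr.unit_text
    if isinstance(expr, Un):
        return _literal_unit(expr.operand)
    if isinstance(expr, Bin):
        return _literal_unit(expr.left) or _literal_unit(expr.right)
    return None


def parse_model(source_text: str) -> ModelDef:
    """Parse model source text into a :class:`ModelDef`.

    Comments (``//`` and ``/* */``) are stripped by the lexer; the
    ``unit conversion on;`` pragma is recorded on the model; declaration
    order within the math block is irrelevant (resolution is a second pass,
    see :func:`resolve_declarations`).
    """
    model = _Parser(tokenize(source_text)).parse_file()
    resolve_declarations(model)  # fail fast on undeclared/duplicate names
    return model


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

@dataclass
class SymbolTable:
    """Classification of every identifier in a resolved model."""

    model: ModelDef
    kinds: dict[str, str]          # name -> domain|parameter|variable|extern
    derivatives: dict[str, tuple[str, str, int]]  # "V:x:x" -> (var, dom, order)

    def kind(self, name: str) -> str:
        return self.kinds[name]


def expr_symbols(expr: Expr) -> set[str]:
    """All bare identifiers referenced by an expression (derivative bases
    and domain-property owners included)."""
    out: set[str] = set()

    def walk(e: Expr) -> None:
        if isinstance(e, Name):
            out.add(e.id)
        elif isinstance(e, Prop):
            out.add(e.domain)
        elif isinstance(e, Deriv):
            out.add(e.var)
            out.update(e.domains)
        elif isinstance(e, Un):
            walk(e.operand)
        elif isinstance(e, Bin):
            walk(e.left)
            walk(e.right)
        elif isinstance(e, Call):
            for a in e.args:
                walk(a)

    walk(expr)
    return out


def expr_derivs(expr: Expr) -> list[Deriv]:
    out: list[Deriv] = []

    def walk(e: Expr) -> None:
        if isinstance(e, Deriv):
            out.append(e)
        elif isinstance(e, Un):
            walk(e.operand)
        elif isinstance(e, Bin):
            walk(e.left)
            walk(e.right)
        elif isinstance(e, Call):
            for a in e.args:
                walk(a)

    walk(expr)
    return out


def resolve_declarations(model: ModelDef) -> SymbolTable:
    """Map every identifier to exactly one symbol class and validate all
    references (undeclared names, duplicate declarations, derivative/domain
    mismatches)."""
    kinds: dict[str, str] = {}

    def declare(name: str, kind: str, line: int) -> None:
        if name in kinds:
            raise MmlResolutionError(f"duplicate declaration of {name!r}", line, 0)
        kinds[name] = kind

    for d in model.domains:
        declare(d.name, "domain", d.line)
    for p in model.params:
        declare(p.name, "parameter", p.line)
    for v in model.variables:
        declare(v.name, "extern" if v.extern else "variable", v.line)
        for dom in v.domains:
            if dom not in kinds or kinds[dom] != "domain":
                raise MmlResolutionError(
                    f"variable {v.name!r} declared on undeclared domain {dom!r}",
                    v.line, 0)

    derivatives: dict[str, tuple[str, str, int]] = {}

    def check_expr(expr: Expr, line: int) -> None:
        for name in expr_symbols(expr):
            if name not in kinds:
                raise MmlResolutionError(f"reference to undeclared identifier "
                                         f"{name!r}", line, 0)
        for d in expr_derivs(expr):
            if kinds.get(d.var) not in ("variable", "extern"):
                raise MmlResolutionError(
                    f"derivative of non-variable {d.var!r}", line, 0)
            vdecl = model.variable(d.var)
            for dom in d.domains:
                if dom not in vdecl.domains:
                    raise MmlResolutionError(
                        f"derivative of {d.var!r} w.r.t. {dom!r}, but "
                        f"{d.var!r} is not declared on {dom!r}", line, 0)
            if d.order == 2 and d.domains[0] != d.domains[1]:
                raise MmlResolutionError(
                    f"mixed second derivative {d.key!r} is not supported",
                    line, 0)
            derivatives[d.key] = (d.var, d.domains[0], d.order)

    for p in model.params:
        check_expr(p.value, p.line)
    for d in model.domains:
        for expr in d.props.values():
            check_expr(expr, d.line)
    for eq in model.equations:
        if eq.guard is not None and kinds.get(eq.guard.domain) != "domain":
            raise MmlResolutionError(
                f"when-guard over undeclared domain {eq.guard.domain!r}",
                eq.line, eq.col)
        check_expr(eq.lhs, eq.line)
        check_expr(eq.rhs, eq.line)

    return SymbolTable(model=model, kinds=kinds, derivatives=derivatives)


# ---------------------------------------------------------------------------
# Constant folding of parameter values / domain grids
# ---------------------------------------------------------------------------

def resolve_param_values(model: ModelDef,
                         overrides: dict[str, float] | None = None
                         ) -> dict[str, float]:
    """Numeric value of every parameter, following references between
    parameters (e.g. ``x.max = L`` needs L first).  ``overrides`` replaces
    declared values by name."""
    overrides = overrides or {}
    values: dict[str, float] = {}
    pending = {p.name: p.value for p in model.params}
    for _ in range(len(pending) + 1):
        progressed = False
        for name, expr in list(pending.items()):
            if name in overrides:
                values[name] = float(overrides[name])
                del pending[name]
                progressed = True
                continue
            try:
                values[name] = eval_const(expr, values)
            except KeyError:
                continue
            del pending[name]
            progressed = True
        if not pending:
            break
        if not progressed:
            raise MmlResolutionError(
                "circular or unresolvable parameter initializers: "
                + ", ".join(sorted(pending)))
    unknown = set(overrides) - {p.name for p in model.params}
    if unknown:
        raise MmlResolutionError(
            f"override of undeclared parameter(s): {sorted(unknown)}")
    return values


def eval_const(expr: Expr, env: dict[str, float]) -> float:
    """Evaluate a constant expression over parameter values (KeyError if an
    identifier is not yet available)."""
    import math

    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Name):
        return env[expr.id]
    if isinstance(expr, Un):
        return -eval_const(expr.operand, env)
    if isinstance(expr, Bin):
        a = eval_const(expr.left, env)
        b = eval_const(expr.right, env)
        return {"+": a + b, "-": a - b, "*": a * b, "/": a / b,
                "^": a ** b}[expr.op]
    if isinstance(expr, Call):
        fns = {"exp": math.exp, "ln": math.log, "log": math.log10,
               "sqrt": math.sqrt, "abs": abs, "sin": math.sin, "cos": math.cos}
        return fns[expr.fn](*(eval_const(a, env) for a in expr.args))
    if isinstance(expr, (Prop, Deriv)):
        return env[_env_key(expr)]
    raise TypeError(type(expr))


def resolve_domain_grid(model: ModelDef, dom: DomainDecl,
                        param_values: dict[str, float],
                        prop_overrides: dict[str, float] | None = None
                        ) -> tuple[float, float, int]:
    """Resolve (min, max, ct) for a domain; grid is uniform and inclusive.

    If ``delta`` is given, ``ct = round((max - min)/delta) + 1``.
    ``prop_overrides`` may replace declared properties at run time using
    dotted keys (``{"t.max": 300.0, "t.delta": 2.0}``); an overridden
    delta/ct takes precedence over the declared grid determinant.
    """
    props = dom.props
    ov = prop_overrides or {}

    def get(prop: str):
        key = f"{dom.name}.{prop}"
        if key in ov:
            return float(ov[key])
        if prop in props:
            return eval_const(props[prop], param_values)
        return None

    lo, hi = get("min"), get("max")
    if lo is None or hi is None:
        raise MmlResolutionError(f"domain {dom.name!r} missing min/max")
    if not hi > lo:
        raise MmlResolutionError(f"domain {dom.name!r}: max must exceed min")
    if f"{dom.name}.delta" in ov:
        delta, ct = float(ov[f"{dom.name}.delta"]), None
    elif f"{dom.name}.ct" in ov:
        delta, ct = None, int(round(float(ov[f"{dom.name}.ct"])))
    elif ("delta" in props) == ("ct" in props):
        raise MmlResolutionError(
            f"domain {dom.name!r}: exactly one of delta/ct must be given")
    elif "delta" in props:
        delta, ct = get("delta"), None
    else:
        delta, ct = None, int(round(get("ct")))
    if delta is not None:
        if delta <= 0:
            raise MmlResolutionError(f"domain {dom.name!r}: delta must be > 0")
        ct = int(round((hi - lo) / delta)) + 1
    if ct < 2:
        raise MmlResolutionError(f"domain {dom.name!r}: ct must be >= 2")
    return lo, hi, ct


# ---------------------------------------------------------------------------
# Expression compilation (shared by all engines)
# ---------------------------------------------------------------------------

def _env_key(expr: Expr) -> str:
    if isinstance(expr, Name):
        return expr.id
    if isinstance(expr, Prop):
        return f"{expr.domain}.{expr.prop}"
    if isinstance(expr, Deriv):
        return expr.key
    raise TypeError(type(expr))


_NUMPY_FNS = {"exp": "exp", "ln": "log", "log": "log10", "sqrt": "sqrt",
              "abs": "abs", "sin": "sin", "cos": "cos"}


def _emit(expr: Expr) -> str:
    if isinstance(expr, Num):
        return repr(expr.value)
    if isinstance(expr, (Name, Prop, Deriv)):
        return f"_e[{_env_key(expr)!r}]"
    if isinstance(expr, Un):
        return f"(-{_emit(expr.operand)})"
    if isinstance(expr, Bin):
        op = "**" if expr.op == "^" else expr.op
        return f"({_emit(expr.left)}{op}{_emit(expr.right)})"
    if isinstance(expr, Call):
        args = ",".join(_emit(a) for a in expr.args)
        return f"_np.{_NUMPY_FNS[expr.fn]}({args})"
    raise TypeError(type(expr))


def compile_expr(expr: Expr):
    """Compile an expression tree to ``f(env) -> value``.

    ``env`` maps identifiers (``"H"``), domain properties (``"t.min"``) and
    derivative slots (``"Ccap:x"``, ``"Ccap:x:x"``) to scalars or numpy
    arrays; evaluation broadcasts.
    """
    import numpy as _np

    src = _emit(expr)
    code = compile(src, "<mml-expr>", "eval")

    def fn(env, _code=code, _np=_np):
        return eval(_code, {"_np": _np, "__builtins__": {"abs": abs}},
                    {"_e": env})

    fn.source = src  # type: ignore[attr-defined]
    return fn


# ---------------------------------------------------------------------------
# Pretty printing
# ---------------------------------------------------------------------------

def _fmt_expr(expr: Expr, parent_prec: int = 0) -> str:
    PREC = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 3}
    if isinstance(expr, Num):
        s = repr(expr.value)
        return f"{s} {expr.unit_text}" if expr.unit_text else s
    if isinstance(expr, Name):
        return expr.id
    if isinstance(expr, Prop):
        return f"{expr.domain}.{expr.prop}"
    if isinstance(expr, Deriv):
        return expr.key
    if isinstance(expr, Un):
        inner = _fmt_expr(expr.operand, 4)
        s = f"-{inner}"
        return f"({s})" if parent_prec > 2 else s
    if isinstance(expr, Bin):
        prec = PREC[expr.op]
        left = _fmt_expr(expr.left, prec)
        right = _fmt_expr(expr.right, prec + 1)  # left-assoc
        s = f"{left}{expr.op}{right}"
        return f"({s})" if prec < parent_prec else s
    if isinstance(expr, Call):
        return f"{expr.fn}({', '.join(_fmt_expr(a) for a in expr.args)})"
    raise TypeError(type(expr))


def pretty_print(model: ModelDef) -> str:
    """Canonical source text; reparses to a structurally identical model."""
    lines: list[str] = []
    for imp in model.imports:
        lines.append(f"import {imp};")
    if model.unit_conversion:
        lines.append("unit conversion on;")
    lines.append(f"math {model.name} {{")
    for d in model.domains:
        unit = f" {d.unit_text}" if d.unit_text != "dimensionless" else ""
        lines.append(f"  realDomain {d.name}{unit};")
        for prop in ("min", "max", "delta", "ct"):
            if prop in d.props:
                lines.append(f"  {d.name}.{prop} = {_fmt_expr(d.props[prop])};")
    for p in model.params:
        lines.append(f"  real {p.name} = {_fmt_expr(p.value)};")
    for v in model.variables:
        prefix = "extern real" if v.extern else "real"
        unit = f" {v.unit_text}" if v.unit_text != "dimensionless" else ""
        lines.append(f"  {prefix} {v.name}({', '.join(v.domains)}){unit};")
    # group consecutive equations sharing a guard into one when clause
    i = 0
    eqs = model.equations
    while i < len(eqs):
        eq = eqs[i]
        if eq.guard is None:
            lines.append(f"  {_fmt_expr(eq.lhs)} = {_fmt_expr(eq.rhs)};")
            i += 1
            continue
        j = i
        while j < len(eqs) and eqs[j].guard == eq.guard:
            j += 1
        g = eq.guard
        lines.append(f"  when ({g.domain}={g.domain}.{g.edge}) {{")
        for k in range(i, j):
            lines.append(f"    {_fmt_expr(eqs[k].lhs)} = {_fmt_expr(eqs[k].rhs)};")
        lines.append("  }")
        i = j
    lines.append("}")
    return "\n".join(lines) + "\n"
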
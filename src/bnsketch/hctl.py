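"""Hybrid CTL (HCTL): syntax, parser, printer, desugaring.

HCTL extends CTL with *state variables* that can be bound to concrete
states: ``!{x}:`` (bind) names the current state ``x``, ``@{x}:`` (jump)
re-anchors evaluation at the state stored in ``x``, and ``3{x}:`` / ``V{x}:``
quantify ``x`` over all states.  This is what lets a single formula speak
about attractors without naming concrete states: ``!{x}: AG EF {x}`` holds
exactly in the states of the attractors of an asynchronous Boolean network
(you can always come back to where you started).

Concrete syntax
---------------
``0 1 true false`` constants, bare identifiers for network variables,
``{x}`` state variables, ``~ & | => <=>`` Boolean connectives,
``EX EF EG AX AF AG`` unary temporal operators, ``E[p U q]`` / ``A[p U q]``
until operators, and the binders ``!{x}:``, ``@{x}:``, ``3{x}:``, ``V{x}:``.
Binders extend as far to the right as possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

__all__ = [
    "HCTLFormula", "HConst", "HProp", "HSVar", "HNot", "HAnd", "HOr", "HImp",
    "HIff", "HEX", "HEF", "HEG", "HAX", "HAF", "HAG", "HEU", "HAU",
    "HAt", "HBind", "HExists", "HForall",
    "HCTLParseError", "parse_hctl", "format_hctl", "free_svars",
    "check_closed", "desugar", "alpha_rename", "quantified_names",
    "attractor_formula", "fixed_point_formula", "shared_basin_formula",
]


class HCTLFormula:
    __slots__ = ()


@dataclass(frozen=True)
class HConst(HCTLFormula):
    value: int


@dataclass(frozen=True)
class HProp(HCTLFormula):
    name: str


@dataclass(frozen=True)
class HSVar(HCTLFormula):
    name: str


@dataclass(frozen=True)
class HNot(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HAnd(HCTLFormula):
    left: HCTLFormula
    right: HCTLFormula


@dataclass(frozen=True)
class HOr(HCTLFormula):
    left: HCTLFormula
    right: HCTLFormula


@dataclass(frozen=True)
class HImp(HCTLFormula):
    left: HCTLFormula
    right: HCTLFormula


@dataclass(frozen=True)
class HIff(HCTLFormula):
    left: HCTLFormula
    right: HCTLFormula


@dataclass(frozen=True)
class HEX(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HEF(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HEG(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HAX(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HAF(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HAG(HCTLFormula):
    arg: HCTLFormula


@dataclass(frozen=True)
class HEU(HCTLFormula):
    left: HCTLFormula
    right: HCTLFormula


@dataclass(frozen=True)
class HAU(HCTLFormula):
    left: HCTLFormula
    right: HCTLFormula


@dataclass(frozen=True)
class HAt(HCTLFormula):
    var: str
    arg: HCTLFormula


@dataclass(frozen=True)
class HBind(HCTLFormula):
    var: str
    arg: HCTLFormula


@dataclass(frozen=True)
class HExists(HCTLFormula):
    var: str
    arg: HCTLFormula


@dataclass(frozen=True)
class HForall(HCTLFormula):
    var: str
    arg: HCTLFormula


_UNARY_TEMPORAL = {"EX": HEX, "EF": HEF, "EG": HEG, "AX": HAX, "AF": HAF, "AG": HAG}
_RESERVED = set(_UNARY_TEMPORAL) | {"E", "A", "U", "true", "false", "V"}


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class HCTLParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_IDENT_START = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ_")
_IDENT_CONT = _IDENT_START | set("0123456789")


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens: List[Tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "!3V@" and i + 1 < n and text[i + 1] == "{":
            j = text.find("}", i + 2)
            if j < 0:
                raise HCTLParseError("unterminated state variable", i)
            name = text[i + 2:j].strip()
            k = j + 1
            while k < n and text[k].isspace():
                k += 1
            if k >= n or text[k] != ":":
                raise HCTLParseError("binder must be followed by ':'", j + 1)
            tokens.append(("binder", c + ":" + name, i))
            i = k + 1
        elif c == "{":
            j = text.find("}", i + 1)
            if j < 0:
                raise HCTLParseError("unterminated state variable", i)
            tokens.append(("svar", text[i + 1:j].strip(), i))
            i = j + 1
        elif c in _IDENT_START:
            j = i + 1
            while j < n and text[j] in _IDENT_CONT:
                j += 1
            tokens.append(("ident", text[i:j], i))
            i = j
        elif c in "01":
            tokens.append(("const", c, i))
            i += 1
        elif text.startswith("<=>", i):
            tokens.append(("op", "<=>", i))
            i += 3
        elif text.startswith("=>", i):
            tokens.append(("op", "=>", i))
            i += 2
        elif c in "~&|()[]":
            tokens.append(("op", c, i))
            i += 1
        else:
            raise HCTLParseError(f"unexpected character {c!r}", i)
    tokens.append(("eof", "", n))
    return tokens


_BINDER_NODE = {"!": HBind, "@": HAt, "3": HExists, "V": HForall}


class _Renamer:
    """Allocates globally unique names for quantified state variables."""

    def __init__(self) -> None:
        self.used: Set[str] = set()

    def fresh(self, base: str) -> str:
        if base not in self.used:
            self.used.add(base)
            return base
        k = 1
        while f"{base}_{k}" in self.used:
            k += 1
        name = f"{base}_{k}"
        self.used.add(name)
        return name


class _HCTLParser:
    def __init__(self, text: str, variables: Sequence[str]):
        self.tokens = _tokenize(text)
        self.pos = 0
        self.variables = set(variables)
        bad = self.variables & _RESERVED
        if bad:
            raise ValueError(f"network variable names collide with reserved words: {sorted(bad)}")
        self.renamer = _Renamer()
        self.scope: List[Tuple[str, str]] = []  # (surface name, unique name)

    def peek(self) -> Tuple[str, str, int]:
        return self.tokens[self.pos]

    def next(self) -> Tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect_op(self, value: str) -> None:
        kind, val, at = self.next()
        if val != value:
            raise HCTLParseError(f"expected {value!r}, found {val or 'end of input'!r}", at)

    def lookup(self, surface: str) -> str:
        for name, unique in reversed(self.scope):
            if name == surface:
                return unique
        # free variable: keep the surface name (reported by check_closed)
        return surface

    def parse(self) -> HCTLFormula:
        f = self.formula()
        kind, val, at = self.peek()
        if kind != "eof":
            raise HCTLParseError(f"trailing input {val!r}", at)
        return f

    def formula(self) -> HCTLFormula:
        kind, val, at = self.peek()
        if kind == "binder":
            self.next()
            op, surface = val[0], val[2:]
            if op == "@":
                # jump does not bind; the referenced variable must resolve
                unique = self.lookup(surface)
                return HAt(unique, self.formula())
            unique = self.renamer.fresh(surface)
            self.scope.append((surface, unique))
            body = self.formula()
            self.scope.pop()
            return _BINDER_NODE[op](unique, body)
        return self.iff()

    def iff(self) -> HCTLFormula:
        f = self.imp()
        while self.peek()[1] == "<=>":
            self.next()
            f = HIff(f, self.imp())
        return f

    def imp(self) -> HCTLFormula:
        f = self.disj()
        if self.peek()[1] == "=>":
            self.next()
            return HImp(f, self.imp())
        return f

    def disj(self) -> HCTLFormula:
        f = self.conj()
        while self.peek()[1] == "|":
            self.next()
            f = HOr(f, self.conj())
        return f

    def conj(self) -> HCTLFormula:
        f = self.unary()
        while self.peek()[1] == "&":
            self.next()
            f = HAnd(f, self.unary())
        return f

    def unary(self) -> HCTLFormula:
        kind, val, at = self.peek()
        if val == "~":
            self.next()
            return HNot(self.unary())
        if kind == "ident" and val in _UNARY_TEMPORAL:
            self.next()
            return _UNARY_TEMPORAL[val](self.unary())
        if kind == "ident" and val in ("E", "A"):
            self.next()
            self.expect_op("[")
            left = self.formula()
            kind2, val2, at2 = self.next()
            if val2 != "U":
                raise HCTLParseError(f"expected 'U', found {val2!r}", at2)
            right = self.formula()
            self.expect_op("]")
            return (HEU if val == "E" else HAU)(left, right)
        if kind == "binder":
            return self.formula()
        return self.atom()

    def atom(self) -> HCTLFormula:
        kind, val, at = self.next()
        if kind == "const":
            return HConst(int(val))
        if kind == "ident" and val in ("true", "false"):
            return HConst(1 if val == "true" else 0)
        if val == "(":
            f = self.formula()
            self.expect_op(")")
            return f
        if kind == "svar":
            return HSVar(self.lookup(val))
        if kind == "ident":
            if val not in self.variables:
                raise HCTLParseError(f"unknown proposition {val!r}", at)
            return HProp(val)
        raise HCTLParseError(f"unexpected token {val or 'end of input'!r}", at)


def parse_hctl(text: str, variables: Sequence[str]) -> HCTLFormula:
    """Parse an HCTL formula; quantified state variables are made unique."""
    return _HCTLParser(text, variables).parse()


# ---------------------------------------------------------------------------
# Printer
# ---------------------------------------------------------------------------

_H_BINARY = {HAnd: "&", HOr: "|", HImp: "=>", HIff: "<=>"}
_H_PREC = {HIff: 1, HImp: 2, HOr: 3, HAnd: 4}
_H_UNARY = {HEX: "EX", HEF: "EF", HEG: "EG", HAX: "AX", HAF: "AF", HAG: "AG"}
_H_BINDER = {HBind: "!", HAt: "@", HExists: "3", HForall: "V"}


def format_hctl(f: HCTLFormula) -> str:
    """Concrete-syntax rendering; ``parse . format`` is the identity."""

    def go(f: HCTLFormula, parent: int) -> str:
        if isinstance(f, HConst):
            return str(f.value)
        if isinstance(f, HProp):
            return f.name
        if isinstance(f, HSVar):
            return "{%s}" % f.name
        if isinstance(f, (HBind, HAt, HExists, HForall)):
            text = f"{_H_BINDER[type(f)]}{{{f.var}}}: {go(f.arg, 0)}"
            return f"({text})" if parent > 0 else text
        if isinstance(f, HNot):
            return "~" + go(f.arg, 5)
        if isinstance(f, tuple(_H_UNARY)):
            return f"{_H_UNARY[type(f)]} {go(f.arg, 5)}"
        if isinstance(f, HEU):
            return f"E[{go(f.left, 0)} U {go(f.right, 0)}]"
        if isinstance(f, HAU):
            return f"A[{go(f.left, 0)} U {go(f.right, 0)}]"
        op = _H_BINARY[type(f)]
        prec = _H_PREC[type(f)]
        if type(f) is HImp:
            text = f"{go(f.left, prec + 1)} {op} {go(f.right, prec)}"
        else:
            text = f"{go(f.left, prec)} {op} {go(f.right, prec + 1)}"
        return f"({text})" if prec < parent else text

    return go(f, 0)


# ---------------------------------------------------------------------------
# Structural helpers
# ---------------------------------------------------------------------------

def free_svars(f: HCTLFormula) -> frozenset[str]:
    if isinstance(f, HSVar):
        return frozenset([f.name])
    if isinstance(f, (HConst, HProp)):
        return frozenset()
    if isinstance(f, (HNot, HEX, HEF, HEG, HAX, HAF, HAG)):
        return free_svars(f.arg)
    if isinstance(f, (HAnd, HOr, HImp, HIff, HEU, HAU)):
        return free_svars(f.left) | free_svars(f.right)
    if isinstance(f, HAt):
        return free_svars(f.arg) | frozenset([f.var])
    if isinstance(f, (HBind, HExists, HForall)):
        return free_svars(f.arg) - frozenset([f.var])
    raise TypeError(f"not an HCTL formula: {f!r}")


def check_closed(f: HCTLFormula) -> bool:
    """True iff the formula has no free state variables."""
    return not free_svars(f)


def quantified_names(f: HCTLFormula) -> frozenset[str]:
    """All state-variable names bound anywhere in the formula."""
    if isinstance(f, (HConst, HProp, HSVar)):
        return frozenset()
    if isinstance(f, (HNot, HEX, HEF, HEG, HAX, HAF, HAG)):
        return quantified_names(f.arg)
    if isinstance(f, (HAnd, HOr, HImp, HIff, HEU, HAU)):
        return quantified_names(f.left) | quantified_names(f.right)
    if isinstance(f, HAt):
        return quantified_names(f.arg)
    if isinstance(f, (HBind, HExists, HForall)):
        return quantified_names(f.arg) | frozenset([f.var])
    raise TypeError(f"not an HCTL formula: {f!r}")


def alpha_rename(f: HCTLFormula) -> HCTLFormula:
    """Make every quantified state variable unique (free names untouched)."""
    renamer = _Renamer()
    renamer.used |= free_svars(f)

    def go(f: HCTLFormula, scope: Dict[str, str]) -> HCTLFormula:
        if isinstance(f, (HConst, HProp)):
            return f
        if isinstance(f, HSVar):
            return HSVar(scope.get(f.name, f.name))
        if isinstance(f, (HNot, HEX, HEF, HEG, HAX, HAF, HAG)):
            return type(f)(go(f.arg, scope))  # type: ignore[call-arg]
        if isinstance(f, (HAnd, HOr, HImp, HIff, HEU, HAU)):
            return type(f)(go(f.left, scope), go(f.right, scope))  # type: ignore[call-arg]
        if isinstance(f, HAt):
            return HAt(scope.get(f.var, f.var), go(f.arg, scope))
        if isinstance(f, (HBind, HExists, HForall)):
            unique = renamer.fresh(f.var)
            inner = dict(scope)
            inner[f.var] = unique
            return type(f)(unique, go(f.arg, inner))  # type: ignore[call-arg]
        raise TypeError(f"not an HCTL formula: {f!r}")

    return go(f, {})


def desugar(f: HCTLFormula) -> HCTLFormula:
    """Rewrite to the core fragment.

    ``EF p = E[1 U p]``, ``AF p = A[1 U p]``, ``EG = ~AF~``, ``AG = ~EF~``,
    ``AX = ~EX~``, ``V{x} = ~3{x}~``, and ``| => <=>`` via ``~ &``.
    """
    if isinstance(f, (HConst, HProp, HSVar)):
        return f
    if isinstance(f, HNot):
        return HNot(desugar(f.arg))
    if isinstance(f, HAnd):
        return HAnd(desugar(f.left), desugar(f.right))
    if isinstance(f, HOr):
        return HNot(HAnd(HNot(desugar(f.left)), HNot(desugar(f.right))))
    if isinstance(f, HImp):
        return HNot(HAnd(desugar(f.left), HNot(desugar(f.right))))
    if isinstance(f, HIff):
        l, r = desugar(f.left), desugar(f.right)
        return HNot(HAnd(HNot(HAnd(l, r)), HNot(HAnd(HNot(l), HNot(r)))))
    if isinstance(f, HEX):
        return HEX(desugar(f.arg))
    if isinstance(f, HEF):
        return HEU(HConst(1), desugar(f.arg))
    if isinstance(f, HAF):
        return HAU(HConst(1), desugar(f.arg))
    if isinstance(f, HEG):
        return HNot(HAU(HConst(1), HNot(desugar(f.arg))))
    if isinstance(f, HAG):
        return HNot(HEU(HConst(1), HNot(desugar(f.arg))))
    if isinstance(f, HAX):
        return HNot(HEX(HNot(desugar(f.arg))))
    if isinstance(f, HEU):
        return HEU(desugar(f.left), desugar(f.right))
    if isinstance(f, HAU):
        return HAU(desugar(f.left), desugar(f.right))
    if isinstance(f, HAt):
        return HAt(f.var, desugar(f.arg))
    if isinstance(f, HBind):
        return HBind(f.var, desugar(f.arg))
    if isinstance(f, HExists):
        return HExists(f.var, desugar(f.arg))
    if isinstance(f, HForall):
        return HNot(HExists(f.var, HNot(desugar(f.arg))))
    raise TypeError(f"not an HCTL formula: {f!r}")


# ---------------------------------------------------------------------------
# Named formulae
# ---------------------------------------------------------------------------

def attractor_formula() -> HCTLFormula:
    """States lying in some attractor: ``!{x}: AG EF {x}``.

    From any state reachable from x one can return to x, which is exactly
    membership of x in a bottom strongly connected component of the STG.
    """
    return HBind("x", HAG(HEF(HSVar("x"))))


def fixed_point_formula() -> HCTLFormula:
    """Fixed points (singleton attractors): ``!{x}: AX {x}``.

    Relies on the convention that steady states carry a self-loop, which
    keeps the transition relation total.
    """
    return HBind("x", HAX(HSVar("x")))


def shared_basin_formula() -> HCTLFormula:
    """Two distinct attractors reachable from one state (a shared weak basin).

    ``3{a}: 3{b}: 3{c}: @{c}: (EF {a} & EF {b} & (@{a}: !{x}: AG EF {x})
    & (@{b}: ((!{y}: AG EF {y}) & ~EF {a})))`` — a and b are attractor
    states, both reachable from c, and b cannot reach a (so they lie in
    different attractors).
    """
    in_attr_x = HBind("x", HAG(HEF(HSVar("x"))))
    in_attr_y = HBind("y", HAG(HEF(HSVar("y"))))
    body = HAnd(
        HAnd(
            HAnd(HEF(HSVar("a")), HEF(HSVar("b"))),
            HAt("a", in_attr_x),
        ),
        HAt("b", HAnd(in_attr_y, HNot(HEF(HSVar("a"))))),
    )
    return HExists("a", HExists("b", HExists("c", HAt("c", body))))
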
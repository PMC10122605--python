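"""Influence graphs, update-function properties, and the sketch container.

A *sketch* bundles everything a modeller knows about a Boolean network
before inference:

* an influence graph ``I`` bounding which variables may regulate which;
* a partially specified Boolean network ``E`` (update expressions with
  uninterpreted function symbols);
* first-order *update-function properties* ``Pi`` (essentiality,
  monotonicity, canalization, veto) constraining the admissible
  interpretations of those symbols;
* a set ``Omega`` of closed HCTL formulae constraining the dynamics.

A concrete network is consistent with the sketch when it satisfies all four
components; inference computes all of them at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import hctl as H
from . import psbn as P
from .engine import SymbolicSet, SymbolicUniverse, compile_expression

__all__ = [
    "InfluenceGraph", "FunctionProperty", "Essential", "Positive", "Negative",
    "Canalizing", "Veto", "PNot", "PAnd", "POr", "PImp", "UFPItem", "Sketch",
    "check_ig_consistency", "count_ig_consistent", "evaluate_property",
    "ufp_constraint", "parse_property", "format_property",
]


# ---------------------------------------------------------------------------
# Influence graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfluenceGraph:
    """Admissible regulator -> target dependencies.

    An edge ``(u, v)`` permits (but does not require) the update function of
    ``v`` to depend on ``u``.  Optional per-edge annotations record a
    regulation sign (``+``/``-``/``?``) and whether the edge is *essential*
    (must actually influence the target); these are used to auto-generate
    function properties, not enforced by the graph itself.
    """

    variables: Tuple[str, ...]
    edges: FrozenSet[Tuple[str, str]]
    signs: Mapping[Tuple[str, str], str] = field(default_factory=dict)
    essential: FrozenSet[Tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        vars_ = set(self.variables)
        for u, v in self.edges:
            if u not in vars_ or v not in vars_:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown variables")
        for key in set(self.signs) | set(self.essential):
            if key not in self.edges:
                raise ValueError(f"annotation on non-edge {key!r}")
        for sign in self.signs.values():
            if sign not in ("+", "-", "?"):
                raise ValueError(f"unknown sign {sign!r}")

    def predecessors(self, target: str) -> Tuple[str, ...]:
        """Regulators of ``target``, in network variable order."""
        incoming = {u for (u, v) in self.edges if v == target}
        return tuple(v for v in self.variables if v in incoming)


def check_ig_consistency(psbn: P.PSBN, ig: InfluenceGraph) -> bool:
    """Syntactic check: every expression only mentions allowed regulators."""
    if tuple(psbn.variables) != tuple(ig.variables):
        raise ValueError("PSBN and influence graph use different variables")
    for target, expr in zip(psbn.variables, psbn.expressions):
        allowed = set(ig.predecessors(target))
        if not P.syntactic_inputs(expr) <= allowed:
            return False
    return True


def count_ig_consistent(ig: InfluenceGraph) -> int:
    """Exact number of Boolean networks consistent with the influence graph.

    A network is consistent when every essential input of ``F_i`` is an
    allowed regulator of ``v_i``; any Boolean function of the ``k_i``
    allowed regulators qualifies, hence the closed form
    ``prod_i 2**(2**k_i)`` (arbitrary-precision).
    """
    total = 1
    for v in ig.variables:
        total *= 1 << (1 << len(ig.predecessors(v)))
    return total


# ---------------------------------------------------------------------------
# Update-function properties
# ---------------------------------------------------------------------------

class FunctionProperty:
    __slots__ = ()


@dataclass(frozen=True)
class Essential(FunctionProperty):
    """Input ``var`` actually influences the output for some state."""
    var: str


@dataclass(frozen=True)
class Positive(FunctionProperty):
    """Non-strict positive monotonicity: f(x[i:=0]) implies f(x[i:=1])."""
    var: str


@dataclass(frozen=True)
class Negative(FunctionProperty):
    """Non-strict negative monotonicity: f(x[i:=1]) implies f(x[i:=0])."""
    var: str


@dataclass(frozen=True)
class Canalizing(FunctionProperty):
    """Input value ``in_value`` on ``var`` forces output ``out_value``."""
    var: str
    in_value: int
    out_value: int


@dataclass(frozen=True)
class Veto(FunctionProperty):
    """Input value ``sign`` on ``var`` vetoes the output (forces 0)."""
    var: str
    sign: int


@dataclass(frozen=True)
class PNot(FunctionProperty):
    arg: FunctionProperty


@dataclass(frozen=True)
class PAnd(FunctionProperty):
    left: FunctionProperty
    right: FunctionProperty


@dataclass(frozen=True)
class POr(FunctionProperty):
    left: FunctionProperty
    right: FunctionProperty


@dataclass(frozen=True)
class PImp(FunctionProperty):
    left: FunctionProperty
    right: FunctionProperty


@dataclass(frozen=True)
class UFPItem:
    """A function property applied to the update expression of one variable."""
    target: int
    property: FunctionProperty


def property_atoms(p: FunctionProperty):
    if isinstance(p, (Essential, Positive, Negative, Canalizing, Veto)):
        yield p
    elif isinstance(p, PNot):
        yield from property_atoms(p.arg)
    elif isinstance(p, (PAnd, POr, PImp)):
        yield from property_atoms(p.left)
        yield from property_atoms(p.right)
    else:
        raise TypeError(f"not a function property: {p!r}")


def evaluate_property(p: FunctionProperty, e: P.Expr,
                      u: SymbolicUniverse) -> SymbolicSet:
    """Colours whose interpretation makes the property hold of ``e``.

    ``e`` must already be free of positive-arity symbols (eliminated); the
    first-order quantifiers over states are discharged by reducing over the
    state axis of the compiled expression.
    """
    var_index = {v: i for i, v in enumerate(u.variables)}
    F = compile_expression(e, u).array
    Ffull = np.broadcast_to(F, (u.S,) + F.shape[1:])

    def halves(i: int):
        mask0 = ~u.state_bits[i]
        f0 = Ffull[mask0]  # states with x_i = 0
        f1 = np.take(Ffull, u.flip[i], axis=0)[mask0]  # their partners
        return f0, f1

    def index_of(name: str) -> int:
        if name not in var_index:
            raise KeyError(f"property references unknown variable {name!r}")
        return var_index[name]

    def go(p: FunctionProperty) -> np.ndarray:
        if isinstance(p, Essential):
            f0, f1 = halves(index_of(p.var))
            return (f0 ^ f1).any(axis=0, keepdims=True)
        if isinstance(p, Positive):
            f0, f1 = halves(index_of(p.var))
            return (~f0 | f1).all(axis=0, keepdims=True)
        if isinstance(p, Negative):
            f0, f1 = halves(index_of(p.var))
            return (~f1 | f0).all(axis=0, keepdims=True)
        if isinstance(p, Canalizing):
            i = index_of(p.var)
            mask = u.state_bits[i] if p.in_value else ~u.state_bits[i]
            slab = Ffull[mask]
            want = slab if p.out_value else ~slab
            return want.all(axis=0, keepdims=True)
        if isinstance(p, Veto):
            return go(Canalizing(p.var, p.sign, 0))
        if isinstance(p, PNot):
            return ~go(p.arg)
        if isinstance(p, PAnd):
            return go(p.left) & go(p.right)
        if isinstance(p, POr):
            return go(p.left) | go(p.right)
        if isinstance(p, PImp):
            return ~go(p.left) | go(p.right)
        raise TypeError(f"not a function property: {p!r}")

    return SymbolicSet(u, go(p))


def ufp_constraint(items: Sequence[UFPItem], eliminated: P.PSBN,
                   u: SymbolicUniverse) -> SymbolicSet:
    """Intersection of all property evaluations (full space when empty)."""
    out = u.full_set()
    for item in items:
        if not 0 <= item.target < eliminated.n:
            raise IndexError(f"property target {item.target} out of range")
        expr = eliminated.expressions[item.target]
        out = out & evaluate_property(item.property, expr, u)
    return out


# ---------------------------------------------------------------------------
# Property concrete syntax (used by sketch files and the CLI)
# ---------------------------------------------------------------------------

_ATOMS = {"essential": 1, "positive": 1, "negative": 1, "canalizing": 3, "veto": 2}


class _PropParser:
    """`essential(v3) & ~positive(v1)`-style strings over `~ & | =>`."""

    def __init__(self, text: str, variables: Sequence[str]):
        self.toks = P._tokenize(text)
        self.pos = 0
        self.variables = set(variables)

    def peek(self):
        return self.toks[self.pos]

    def next(self):
        tok = self.toks[self.pos]
        self.pos += 1
        return tok

    def expect(self, value: str):
        kind, val, at = self.next()
        if val != value:
            raise P.ExprParseError(f"expected {value!r}, found {val or 'end of input'!r}", at)

    def parse(self) -> FunctionProperty:
        p = self.imp()
        kind, val, at = self.peek()
        if kind != "eof":
            raise P.ExprParseError(f"trailing input {val!r}", at)
        return p

    def imp(self) -> FunctionProperty:
        p = self.disj()
        if self.peek()[1] == "=>":
            self.next()
            return PImp(p, self.imp())
        return p

    def disj(self) -> FunctionProperty:
        p = self.conj()
        while self.peek()[1] == "|":
            self.next()
            p = POr(p, self.conj())
        return p

    def conj(self) -> FunctionProperty:
        p = self.unary()
        while self.peek()[1] == "&":
            self.next()
            p = PAnd(p, self.unary())
        return p

    def unary(self) -> FunctionProperty:
        kind, val, at = self.peek()
        if val == "!":
            self.next()
            return PNot(self.unary())
        if val == "(":
            self.next()
            p = self.imp()
            self.expect(")")
            return p
        return self.atom()

    def atom(self) -> FunctionProperty:
        kind, val, at = self.next()
        if kind != "ident" or val not in _ATOMS:
            raise P.ExprParseError(
                f"expected one of {sorted(_ATOMS)}, found {val or 'end of input'!r}", at)
        self.expect("(")
        args: List[str] = []
        while True:
            k2, v2, a2 = self.next()
            if k2 not in ("ident", "const"):
                raise P.ExprParseError(f"bad argument {v2!r}", a2)
            args.append(v2)
            k3, v3, a3 = self.next()
            if v3 == ")":
                break
            if v3 != ",":
                raise P.ExprParseError(f"expected ',' or ')', found {v3!r}", a3)
        if len(args) != _ATOMS[val]:
            raise P.ExprParseError(
                f"{val} takes {_ATOMS[val]} argument(s), got {len(args)}", at)
        var = args[0]
        if var not in self.variables:
            raise P.ExprParseError(f"unknown variable {var!r}", at)
        if val == "essential":
            return Essential(var)
        if val == "positive":
            return Positive(var)
        if val == "negative":
            return Negative(var)
        if val == "canalizing":
            return Canalizing(var, int(args[1]), int(args[2]))
        return Veto(var, int(args[1]))


def parse_property(text: str, variables: Sequence[str]) -> FunctionProperty:
    return _PropParser(text, variables).parse()


def format_property(p: FunctionProperty) -> str:
    if isinstance(p, Essential):
        return f"essential({p.var})"
    if isinstance(p, Positive):
        return f"positive({p.var})"
    if isinstance(p, Negative):
        return f"negative({p.var})"
    if isinstance(p, Canalizing):
        return f"canalizing({p.var}, {p.in_value}, {p.out_value})"
    if isinstance(p, Veto):
        return f"veto({p.var}, {p.sign})"
    if isinstance(p, PNot):
        return f"!({format_property(p.arg)})"
    if isinstance(p, PAnd):
        return f"({format_property(p.left)} & {format_property(p.right)})"
    if isinstance(p, POr):
        return f"({format_property(p.left)} | {format_property(p.right)})"
    if isinstance(p, PImp):
        return f"({format_property(p.left)} => {format_property(p.right)})"
    raise TypeError(f"not a function property: {p!r}")


# ---------------------------------------------------------------------------
# The sketch container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sketch:
    """The tuple (influence graph, PSBN, function properties, HCTL formulae)."""

    ig: InfluenceGraph
    psbn: P.PSBN
    ufp: Tuple[UFPItem, ...] = ()
    dynamic: Tuple[H.HCTLFormula, ...] = ()

    def __post_init__(self) -> None:
        if tuple(self.ig.variables) != tuple(self.psbn.variables):
            raise ValueError("influence graph and PSBN variables differ")
        for item in self.ufp:
            if not 0 <= item.target < self.psbn.n:
                raise IndexError(f"property target {item.target} out of range")
        for f in self.dynamic:
            if not H.check_closed(f):
                raise ValueError(
                    f"dynamic property {H.format_hctl(f)!r} has free state variables")

    @property
    def variables(self) -> Tuple[str, ...]:
        return self.psbn.variables
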
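"""Partially specified Boolean networks (PSBNs).

A PSBN is a Boolean network whose update expressions may contain
*uninterpreted function symbols*: fixed but unknown Boolean functions.
Fixing an interpretation (a concrete truth table per symbol) specializes
the PSBN into an ordinary Boolean network.

The central transformation here is :func:`eliminate_symbols`, which rewrites
every application of a symbol of arity ``a > 0`` into a row-selection
expansion over ``2**a`` fresh zero-arity symbols that jointly encode the
symbol's truth table.  After elimination, the remaining zero-arity symbols
act as Boolean *parameters* ("colours"): one valuation of the parameters
corresponds to exactly one interpretation of the original symbols.

Conventions
-----------
* Variables are ordered; a state is a 0/1 tuple in that order.
* A state's row index reads the state as an unsigned binary number with the
  *first* variable most significant.  Truth tables of update functions use
  this row order over the network state; truth tables of interpretations use
  it over the symbol's argument vector (argument 1 most significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "Expr", "Const", "Var", "Not", "And", "Or", "Imp", "Iff", "Xor", "App",
    "FunctionSymbol", "PSBN", "BooleanNetwork", "SymbolTable",
    "ExprParseError", "parse_expression", "syntactic_inputs", "evaluate",
    "specialize", "dep_set", "eliminate_symbols",
    "interpretation_from_constants", "desugar_expr", "format_expression",
    "state_index", "index_state", "all_tables",
]

Interpretation = Mapping[str, Tuple[int, ...]]

DEFAULT_ARITY_CAP = 8


# ---------------------------------------------------------------------------
# States and truth-table row order
# ---------------------------------------------------------------------------

def state_index(bits: Sequence[int]) -> int:
    """Row index of a state: first element is the most significant bit."""
    idx = 0
    for b in bits:
        idx = (idx << 1) | (1 if b else 0)
    return idx


def index_state(idx: int, n: int) -> Tuple[int, ...]:
    """Inverse of :func:`state_index` for vectors of length ``n``."""
    return tuple((idx >> (n - 1 - i)) & 1 for i in range(n))


def all_tables(arity: int) -> Iterable[Tuple[int, ...]]:
    """All truth tables of a Boolean function with ``arity`` inputs."""
    rows = 1 << arity
    for code in range(1 << rows):
        # bit for row 0 is the most significant, so tables enumerate in
        # lexicographic order of their row vector
        yield tuple((code >> (rows - 1 - r)) & 1 for r in range(rows))


# ---------------------------------------------------------------------------
# Abstract syntax
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionSymbol:
    name: str
    arity: int

    def __post_init__(self) -> None:
        if self.arity < 0:
            raise ValueError(f"negative arity for symbol {self.name!r}")


class Expr:
    """Base class of partially specified Boolean expressions."""

    __slots__ = ()


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1


@dataclass(frozen=True)
class Var(Expr):
    name: str
    index: int


@dataclass(frozen=True)
class Not(Expr):
    arg: Expr


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Imp(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Iff(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Xor(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class App(Expr):
    symbol: FunctionSymbol
    args: Tuple[Expr, ...]

    def __post_init__(self) -> None:
        if len(self.args) != self.symbol.arity:
            raise ValueError(
                f"symbol {self.symbol.name!r} has arity {self.symbol.arity}, "
                f"got {len(self.args)} arguments"
            )


_BINARY = {And: "&", Or: "|", Imp: "=>", Iff: "<=>", Xor: "^"}
# looser operators get lower numbers; mirrors the parser's precedence
_PREC = {Iff: 1, Imp: 2, Xor: 3, Or: 4, And: 5, Not: 6}


def format_expression(e: Expr) -> str:
    """Concrete-syntax rendering; inverse of :func:`parse_expression`."""

    def go(e: Expr, parent: int) -> str:
        if isinstance(e, Const):
            return str(e.value)
        if isinstance(e, Var):
            return e.name
        if isinstance(e, App):
            if e.symbol.arity == 0:
                return e.symbol.name
            return f"{e.symbol.name}({', '.join(go(a, 0) for a in e.args)})"
        if isinstance(e, Not):
            return "!" + go(e.arg, _PREC[Not])
        op = _BINARY[type(e)]
        prec = _PREC[type(e)]
        # => is right-associative; the other binary operators are rendered
        # left-associatively, matching the parser
        if type(e) is Imp:
            text = f"{go(e.left, prec + 1)} {op} {go(e.right, prec)}"
        else:
            text = f"{go(e.left, prec)} {op} {go(e.right, prec + 1)}"
        return f"({text})" if prec < parent else text

    return go(e, 0)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class ExprParseError(ValueError):
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
        if c in _IDENT_START:
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
        elif c in "!&|^(),":
            tokens.append(("op", c, i))
            i += 1
        else:
            raise ExprParseError(f"unexpected character {c!r}", i)
    tokens.append(("eof", "", n))
    return tokens


class _ExprParser:
    """Recursive descent over precedence ``! > & > | > ^ > => > <=>``."""

    def __init__(self, text: str, variables: Sequence[str],
                 symbols: Mapping[str, FunctionSymbol]):
        self.tokens = _tokenize(text)
        self.pos = 0
        self.var_index = {v: i for i, v in enumerate(variables)}
        self.symbols = dict(symbols)

    def peek(self) -> Tuple[str, str, int]:
        return self.tokens[self.pos]

    def next(self) -> Tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, at = self.next()
        if val != value:
            raise ExprParseError(f"expected {value!r}, found {val or 'end of input'!r}", at)

    def parse(self) -> Expr:
        e = self.iff()
        kind, val, at = self.peek()
        if kind != "eof":
            raise ExprParseError(f"trailing input {val!r}", at)
        return e

    def iff(self) -> Expr:
        e = self.imp()
        while self.peek()[1] == "<=>":
            self.next()
            e = Iff(e, self.imp())
        return e

    def imp(self) -> Expr:
        e = self.xor()
        if self.peek()[1] == "=>":
            self.next()
            return Imp(e, self.imp())  # right-associative
        return e

    def xor(self) -> Expr:
        e = self.disj()
        while self.peek()[1] == "^":
            self.next()
            e = Xor(e, self.disj())
        return e

    def disj(self) -> Expr:
        e = self.conj()
        while self.peek()[1] == "|":
            self.next()
            e = Or(e, self.conj())
        return e

    def conj(self) -> Expr:
        e = self.unary()
        while self.peek()[1] == "&":
            self.next()
            e = And(e, self.unary())
        return e

    def unary(self) -> Expr:
        kind, val, at = self.peek()
        if val == "!":
            self.next()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Expr:
        kind, val, at = self.next()
        if kind == "const":
            return Const(int(val))
        if val == "(":
            e = self.iff()
            self.expect(")")
            return e
        if kind == "ident":
            if val in self.symbols:
                sym = self.symbols[val]
                args: List[Expr] = []
                if self.peek()[1] == "(":
                    self.next()
                    if self.peek()[1] != ")":
                        args.append(self.iff())
                        while self.peek()[1] == ",":
                            self.next()
                            args.append(self.iff())
                    self.expect(")")
                if len(args) != sym.arity:
                    raise ExprParseError(
                        f"symbol {val!r} has arity {sym.arity}, "
                        f"applied to {len(args)} arguments", at)
                return App(sym, tuple(args))
            if val in self.var_index:
                return Var(val, self.var_index[val])
            raise ExprParseError(f"undeclared identifier {val!r}", at)
        raise ExprParseError(f"unexpected token {val or 'end of input'!r}", at)


def parse_expression(text: str, variables: Sequence[str],
                     symbols: Mapping[str, FunctionSymbol] | Iterable[FunctionSymbol] = ()) -> Expr:
    """Parse a partially specified Boolean expression.

    ``symbols`` may be a mapping name -> :class:`FunctionSymbol` or an
    iterable of symbols.  A zero-arity symbol may be written bare (``f``) or
    applied (``f()``).
    """
    if not isinstance(symbols, Mapping):
        symbols = {s.name: s for s in symbols}
    overlap = set(symbols) & set(variables)
    if overlap:
        raise ValueError(f"identifiers declared both as variable and symbol: {sorted(overlap)}")
    return _ExprParser(text, variables, symbols).parse()


# ---------------------------------------------------------------------------
# Semantics
# ---------------------------------------------------------------------------

def syntactic_inputs(e: Expr) -> frozenset[str]:
    """Names of network variables occurring anywhere in ``e``."""
    out: set[str] = set()

    def go(e: Expr) -> None:
        if isinstance(e, Var):
            out.add(e.name)
        elif isinstance(e, Not):
            go(e.arg)
        elif isinstance(e, (And, Or, Imp, Iff, Xor)):
            go(e.left)
            go(e.right)
        elif isinstance(e, App):
            for a in e.args:
                go(a)

    go(e)
    return frozenset(out)


def expression_symbols(e: Expr) -> Dict[str, FunctionSymbol]:
    """Symbols occurring in ``e``, in depth-first first-occurrence order."""
    out: Dict[str, FunctionSymbol] = {}

    def go(e: Expr) -> None:
        if isinstance(e, Not):
            go(e.arg)
        elif isinstance(e, (And, Or, Imp, Iff, Xor)):
            go(e.left)
            go(e.right)
        elif isinstance(e, App):
            prev = out.setdefault(e.symbol.name, e.symbol)
            if prev.arity != e.symbol.arity:
                raise ValueError(f"symbol {e.symbol.name!r} used with two arities")
            for a in e.args:
                go(a)

    go(e)
    return out


def evaluate(e: Expr, state: Sequence[int], interp: Interpretation) -> int:
    """Value of ``e`` at ``state`` once every symbol is fixed by ``interp``."""
    if isinstance(e, Const):
        return e.value
    if isinstance(e, Var):
        return 1 if state[e.index] else 0
    if isinstance(e, Not):
        return 1 - evaluate(e.arg, state, interp)
    if isinstance(e, And):
        return evaluate(e.left, state, interp) & evaluate(e.right, state, interp)
    if isinstance(e, Or):
        return evaluate(e.left, state, interp) | evaluate(e.right, state, interp)
    if isinstance(e, Imp):
        return (1 - evaluate(e.left, state, interp)) | evaluate(e.right, state, interp)
    if isinstance(e, Iff):
        return 1 - (evaluate(e.left, state, interp) ^ evaluate(e.right, state, interp))
    if isinstance(e, Xor):
        return evaluate(e.left, state, interp) ^ evaluate(e.right, state, interp)
    if isinstance(e, App):
        name = e.symbol.name
        if name not in interp:
            raise KeyError(f"interpretation does not cover symbol {name!r}")
        table = interp[name]
        if len(table) != 1 << e.symbol.arity:
            raise ValueError(f"interpretation of {name!r} has wrong length")
        row = state_index([evaluate(a, state, interp) for a in e.args])
        return 1 if table[row] else 0
    raise TypeError(f"not an expression: {e!r}")


def desugar_expr(e: Expr) -> Expr:
    """Rewrite the sugar operators into the {0, 1, v, not, and, apply} core."""
    if isinstance(e, (Const, Var)):
        return e
    if isinstance(e, Not):
        return Not(desugar_expr(e.arg))
    if isinstance(e, And):
        return And(desugar_expr(e.left), desugar_expr(e.right))
    if isinstance(e, Or):
        return Not(And(Not(desugar_expr(e.left)), Not(desugar_expr(e.right))))
    if isinstance(e, Imp):
        return Not(And(desugar_expr(e.left), Not(desugar_expr(e.right))))
    if isinstance(e, Iff):
        l, r = desugar_expr(e.left), desugar_expr(e.right)
        return Not(And(Not(And(l, r)), Not(And(Not(l), Not(r)))))
    if isinstance(e, Xor):
        l, r = desugar_expr(e.left), desugar_expr(e.right)
        return And(Not(And(l, r)), Not(And(Not(l), Not(r))))
    if isinstance(e, App):
        return App(e.symbol, tuple(desugar_expr(a) for a in e.args))
    raise TypeError(f"not an expression: {e!r}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A fully specified Boolean network: one truth table per variable."""

    variables: Tuple[str, ...]
    tables: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.variables)
        if len(self.tables) != n:
            raise ValueError("one update table required per variable")
        for t in self.tables:
            if len(t) != 1 << n:
                raise ValueError("update tables must have length 2**n")

    @property
    def n(self) -> int:
        return len(self.variables)

    def update(self, state: Sequence[int]) -> Tuple[int, ...]:
        """Synchronous image of ``state`` (all variables updated at once)."""
        row = state_index(state)
        return tuple(t[row] for t in self.tables)


@dataclass(frozen=True)
class PSBN:
    """Ordered variables plus one partially specified expression each."""

    variables: Tuple[str, ...]
    expressions: Tuple[Expr, ...]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        if len(self.expressions) != len(self.variables):
            raise ValueError("one expression required per variable")
        for e in self.expressions:
            for name in syntactic_inputs(e):
                if name not in self.variables:
                    raise ValueError(f"expression references unknown variable {name!r}")

    @property
    def n(self) -> int:
        return len(self.variables)

    def symbols(self) -> Dict[str, FunctionSymbol]:
        """All symbols of the PSBN, in first-occurrence order across E_1..E_n."""
        out: Dict[str, FunctionSymbol] = {}
        for e in self.expressions:
            for name, sym in expression_symbols(e).items():
                prev = out.setdefault(name, sym)
                if prev.arity != sym.arity:
                    raise ValueError(f"symbol {name!r} used with two arities")
        return out


def specialize(psbn: PSBN, interp: Interpretation) -> BooleanNetwork:
    """The concrete network obtained by fixing every symbol of ``psbn``."""
    n = psbn.n
    for name, sym in psbn.symbols().items():
        if name not in interp:
            raise KeyError(f"interpretation does not cover symbol {name!r}")
    tables = []
    for e in psbn.expressions:
        tables.append(tuple(
            evaluate(e, index_state(row, n), interp) for row in range(1 << n)
        ))
    return BooleanNetwork(psbn.variables, tuple(tables))


def dep_set(table: Sequence[int]) -> frozenset[int]:
    """Indices of essential inputs of a truth table of length ``2**n``.

    Input ``j`` is essential iff flipping it changes the output for some
    state.
    """
    size = len(table)
    n = size.bit_length() - 1
    if size != 1 << n:
        raise ValueError("truth-table length must be a power of two")
    deps = set()
    for j in range(n):
        bit = 1 << (n - 1 - j)
        for row in range(size):
            if not row & bit and table[row] != table[row | bit]:
                deps.add(j)
                break
    return frozenset(deps)


# ---------------------------------------------------------------------------
# Symbol elimination
# ---------------------------------------------------------------------------

@dataclass
class SymbolTable:
    """Bookkeeping of the truth-table expansion of uninterpreted symbols.

    ``constants`` lists all zero-arity symbols of the eliminated PSBN in a
    fixed global order: this order defines the *colour* encoding used by the
    symbolic engine (first constant = most significant bit).  For each
    original symbol, ``rows[name]`` lists its ``2**arity`` constants in
    truth-table row order.
    """

    arities: Dict[str, int] = field(default_factory=dict)
    rows: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def constants(self) -> List[str]:
        out: List[str] = []
        for name in self.rows:
            out.extend(self.rows[name])
        return out


def eliminate_symbols(psbn: PSBN, arity_cap: int = DEFAULT_ARITY_CAP) -> Tuple[PSBN, SymbolTable]:
    """Replace every symbol of positive arity by its row-selection expansion.

    ``f(e_1, .., e_a)`` becomes ``OR over rows b of (c_{f,b} AND (e_i <=> b_i
    for all i))`` where the ``c_{f,b}`` are fresh zero-arity symbols encoding
    f's truth table.  Zero-arity symbols pass through unchanged and serve as
    their own constants.
    """
    symbols = psbn.symbols()
    tab = SymbolTable()
    taken = set(psbn.variables) | set(symbols)
    const_syms: Dict[str, List[FunctionSymbol]] = {}
    for name, sym in symbols.items():
        if sym.arity > arity_cap:
            raise ValueError(
                f"symbol {name!r} has arity {sym.arity}, above the cap {arity_cap}")
        tab.arities[name] = sym.arity
        if sym.arity == 0:
            tab.rows[name] = [name]
            const_syms[name] = [sym]
            continue
        row_names: List[str] = []
        row_syms: List[FunctionSymbol] = []
        for row in range(1 << sym.arity):
            bits = format(row, f"0{sym.arity}b")
            cname = f"{name}_{bits}"
            while cname in taken:
                cname += "_"
            taken.add(cname)
            row_names.append(cname)
            row_syms.append(FunctionSymbol(cname, 0))
        tab.rows[name] = row_names
        const_syms[name] = row_syms

    def transform(e: Expr) -> Expr:
        if isinstance(e, (Const, Var)):
            return e
        if isinstance(e, Not):
            return Not(transform(e.arg))
        if isinstance(e, (And, Or, Imp, Iff, Xor)):
            return type(e)(transform(e.left), transform(e.right))  # type: ignore[call-arg]
        if isinstance(e, App):
            args = tuple(transform(a) for a in e.args)
            a = e.symbol.arity
            if a == 0:
                return e
            terms: List[Expr] = []
            for row in range(1 << a):
                sel: Expr = App(const_syms[e.symbol.name][row], ())
                for i in range(a):
                    bit = (row >> (a - 1 - i)) & 1
                    lit = args[i] if bit else Not(args[i])
                    sel = And(sel, lit)
                terms.append(sel)
            out = terms[0]
            for t in terms[1:]:
                out = Or(out, t)
            return out
        raise TypeError(f"not an expression: {e!r}")

    eliminated = PSBN(psbn.variables, tuple(transform(e) for e in psbn.expressions))
    return eliminated, tab


def interpretation_from_constants(tab: SymbolTable,
                                  valuation: Mapping[str, int]) -> Dict[str, Tuple[int, ...]]:
    """Read an interpretation of the original symbols off a constant valuation."""
    out: Dict[str, Tuple[int, ...]] = {}
    for name, row_names in tab.rows.items():
        try:
            out[name] = tuple(1 if valuation[c] else 0 for c in row_names)
        except KeyError as exc:
            raise KeyError(f"valuation does not cover constant {exc.args[0]!r}") from exc
    return out
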
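"""Symbolic universe and the coloured asynchronous state-transition graph.

The engine represents sets of ``(state, state-variable valuation, colour)``
triples as dense Boolean characteristic vectors (numpy arrays).  A *colour*
is a valuation of the zero-arity parameter constants produced by symbol
elimination; one colour corresponds to one interpretation of the original
uninterpreted symbols.  The coloured state-transition graph (STG) encodes
the asynchronous dynamics of *every* candidate network at once: a
transition exists at colour ``c`` exactly when it exists in the network
obtained by specializing under ``c``.

Array layout: axis 0 ranges over the ``2**n`` network states, one axis per
declared state-variable (auxiliary) name, and the last axis over the
``2**m`` colours.  An axis of size 1 means the set does not constrain that
dimension; numpy broadcasting then implements set operations without ever
materializing the full product space.

Row order everywhere: a state (or colour) is read as an unsigned binary
number with the first variable (or constant) most significant, matching the
truth-table convention of :mod:`bnsketch.psbn`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import psbn as P

__all__ = ["SymbolicUniverse", "SymbolicSet", "ColouredSTG",
           "compile_expression", "build_coloured_stg"]

#: refuse to allocate colour spaces above this many parameter constants
MAX_COLOUR_BITS = 24


class SymbolicUniverse:
    """Variable layout shared by all symbolic sets of one inference run."""

    def __init__(self, variables: Sequence[str], constants: Sequence[str],
                 aux_names: Sequence[str] = ()):
        self.variables: Tuple[str, ...] = tuple(variables)
        self.constants: Tuple[str, ...] = tuple(constants)
        self.aux_names: Tuple[str, ...] = tuple(aux_names)
        if len(set(self.aux_names)) != len(self.aux_names):
            raise ValueError("duplicate auxiliary state-variable names")
        self.n = len(self.variables)
        self.m = len(self.constants)
        if self.m > MAX_COLOUR_BITS:
            raise ValueError(
                f"{self.m} parameter constants exceed the supported maximum "
                f"({MAX_COLOUR_BITS}); reduce symbol arities or in-degrees")
        self.S = 1 << self.n
        self.C = 1 << self.m
        self.ndim = 2 + len(self.aux_names)
        self._const_pos = {c: i for i, c in enumerate(self.constants)}
        self._aux_axis = {x: 1 + i for i, x in enumerate(self.aux_names)}
        # state_bits[i][s] = value of variable i in state s
        s = np.arange(self.S)
        self.state_bits = np.stack(
            [((s >> (self.n - 1 - i)) & 1).astype(bool) for i in range(self.n)]
        ) if self.n else np.zeros((0, 1), dtype=bool)
        c = np.arange(self.C)
        self.colour_bits = np.stack(
            [((c >> (self.m - 1 - j)) & 1).astype(bool) for j in range(self.m)]
        ) if self.m else np.zeros((0, 1), dtype=bool)
        # flip[i][s] = s with the value of variable i toggled
        self.flip = np.stack(
            [s ^ (1 << (self.n - 1 - i)) for i in range(self.n)]
        ) if self.n else np.zeros((0, 1), dtype=np.int64)

    # -- axis helpers -----------------------------------------------------

    def aux_axis(self, name: str) -> int:
        if name not in self._aux_axis:
            raise KeyError(f"unknown state variable {name!r}")
        return self._aux_axis[name]

    def _ones(self) -> Tuple[int, ...]:
        return (1,) * self.ndim

    def lift_state(self, bits: np.ndarray) -> np.ndarray:
        """Shape a length-``2**n`` predicate onto the state axis."""
        shape = [1] * self.ndim
        shape[0] = self.S
        return np.asarray(bits, dtype=bool).reshape(shape)

    def lift_aux(self, name: str, bits: np.ndarray) -> np.ndarray:
        shape = [1] * self.ndim
        shape[self.aux_axis(name)] = self.S
        return np.asarray(bits, dtype=bool).reshape(shape)

    def lift_colour(self, bits: np.ndarray) -> np.ndarray:
        shape = [1] * self.ndim
        shape[-1] = self.C
        return np.asarray(bits, dtype=bool).reshape(shape)

    # -- primitive predicates --------------------------------------------

    def state_var(self, i: int) -> "SymbolicSet":
        """States in which network variable ``i`` is true."""
        return SymbolicSet(self, self.lift_state(self.state_bits[i]))

    def colour_const(self, name: str) -> "SymbolicSet":
        """Colours in which parameter constant ``name`` is true."""
        j = self._const_pos[name]
        return SymbolicSet(self, self.lift_colour(self.colour_bits[j]))

    def sv_eq_state(self, name: str) -> "SymbolicSet":
        """Pairs where the valuation of state variable ``name`` equals the
        current state (the diagonal of the state x aux product)."""
        eye = np.eye(self.S, dtype=bool)
        shape = [1] * self.ndim
        shape[0] = self.S
        shape[self.aux_axis(name)] = self.S
        return SymbolicSet(self, eye.reshape(shape))

    def empty_set(self) -> "SymbolicSet":
        return SymbolicSet(self, np.zeros(self._ones(), dtype=bool))

    def full_set(self) -> "SymbolicSet":
        return SymbolicSet(self, np.ones(self._ones(), dtype=bool))


@dataclass(frozen=True)
class SymbolicSet:
    """A Boolean predicate over (state, aux valuations, colour)."""

    universe: SymbolicUniverse
    array: np.ndarray

    def __post_init__(self) -> None:
        if self.array.ndim != self.universe.ndim:
            raise ValueError("array rank does not match the universe layout")
        if self.array.dtype != np.bool_:
            object.__setattr__(self, "array", self.array.astype(bool))

    def _check(self, other: "SymbolicSet") -> None:
        if other.universe is not self.universe:
            raise ValueError("sets belong to different symbolic universes")

    def __and__(self, other: "SymbolicSet") -> "SymbolicSet":
        self._check(other)
        return SymbolicSet(self.universe, self.array & other.array)

    def __or__(self, other: "SymbolicSet") -> "SymbolicSet":
        self._check(other)
        return SymbolicSet(self.universe, self.array | other.array)

    def __xor__(self, other: "SymbolicSet") -> "SymbolicSet":
        self._check(other)
        return SymbolicSet(self.universe, self.array ^ other.array)

    def __invert__(self) -> "SymbolicSet":
        return SymbolicSet(self.universe, ~self.array)

    def minus(self, other: "SymbolicSet") -> "SymbolicSet":
        self._check(other)
        return SymbolicSet(self.universe, self.array & ~other.array)

    def is_empty(self) -> bool:
        return not bool(self.array.any())

    def same_as(self, other: "SymbolicSet") -> bool:
        self._check(other)
        a, b = np.broadcast_arrays(self.array, other.array)
        return bool(np.array_equal(a, b))

    def exists_aux(self, name: str) -> "SymbolicSet":
        """Existentially quantify away one auxiliary state-variable vector."""
        axis = self.universe.aux_axis(name)
        return SymbolicSet(self.universe,
                           self.array.any(axis=axis, keepdims=True))

    def forall_aux(self, name: str) -> "SymbolicSet":
        axis = self.universe.aux_axis(name)
        return SymbolicSet(self.universe,
                           self.array.all(axis=axis, keepdims=True))

    def depends_on_aux(self) -> List[str]:
        """Aux names whose axis is materialized (size > 1)."""
        return [x for x in self.universe.aux_names
                if self.array.shape[self.universe.aux_axis(x)] > 1]

    # -- projections used by decoding and reporting ----------------------

    def colour_vector(self) -> np.ndarray:
        """Project onto colours: colours with at least one satisfying tuple."""
        arr = self.array
        axes = tuple(range(arr.ndim - 1))
        vec = arr.any(axis=axes)
        if vec.shape[0] == 1 and self.universe.C > 1:
            vec = np.broadcast_to(vec, (self.universe.C,)).copy()
        return vec

    def state_vector(self) -> np.ndarray:
        arr = self.array
        axes = tuple(range(1, arr.ndim))
        vec = arr.any(axis=axes)
        if vec.shape[0] == 1 and self.universe.S > 1:
            vec = np.broadcast_to(vec, (self.universe.S,)).copy()
        return vec


# ---------------------------------------------------------------------------
# Expression compilation
# ---------------------------------------------------------------------------

def compile_expression(e: P.Expr, u: SymbolicUniverse) -> SymbolicSet:
    """Predicate over (state, colour) that is true exactly where the
    eliminated expression evaluates to 1 under the colour's interpretation."""

    var_index = {v: i for i, v in enumerate(u.variables)}

    def go(e: P.Expr) -> np.ndarray:
        if isinstance(e, P.Const):
            shape = [1] * u.ndim
            return np.full(shape, bool(e.value))
        if isinstance(e, P.Var):
            return u.lift_state(u.state_bits[var_index[e.name]])
        if isinstance(e, P.Not):
            return ~go(e.arg)
        if isinstance(e, P.And):
            return go(e.left) & go(e.right)
        if isinstance(e, P.Or):
            return go(e.left) | go(e.right)
        if isinstance(e, P.Imp):
            return ~go(e.left) | go(e.right)
        if isinstance(e, P.Iff):
            return ~(go(e.left) ^ go(e.right))
        if isinstance(e, P.Xor):
            return go(e.left) ^ go(e.right)
        if isinstance(e, P.App):
            if e.symbol.arity != 0:
                raise ValueError(
                    f"symbol {e.symbol.name!r} has arity {e.symbol.arity}; "
                    "eliminate symbols before compiling")
            if e.symbol.name not in u._const_pos:
                raise KeyError(f"unknown parameter constant {e.symbol.name!r}")
            return u.colour_const(e.symbol.name).array
        raise TypeError(f"not an expression: {e!r}")

    return SymbolicSet(u, go(e))


# ---------------------------------------------------------------------------
# Coloured STG
# ---------------------------------------------------------------------------

class ColouredSTG:
    """Asynchronous transition structure of all candidate networks at once.

    For each variable ``i`` the array ``update[i]`` holds the compiled value
    of the (eliminated) update expression ``E'_i`` at every (state, colour).
    A transition ``s -> s[i := not s_i]`` exists at colour ``c`` iff
    ``update[i](s, c) != s_i``; a self-loop exists exactly at the fixed
    points, which keeps the relation total.
    """

    def __init__(self, universe: SymbolicUniverse, eliminated: P.PSBN,
                 colours: Optional[SymbolicSet] = None):
        if tuple(eliminated.variables) != universe.variables:
            raise ValueError("universe and PSBN variables differ")
        self.universe = universe
        self.eliminated = eliminated
        u = universe
        self.update: List[np.ndarray] = [
            compile_expression(e, u).array for e in eliminated.expressions
        ]
        self_loop = np.ones((1,) * u.ndim, dtype=bool)
        for i in range(u.n):
            self_loop = self_loop & ~(self.update[i] ^ u.lift_state(u.state_bits[i]))
        self.self_loop = self_loop
        self.colours: SymbolicSet = colours if colours is not None else u.full_set()

    # -- image operators --------------------------------------------------

    @staticmethod
    def _take_flip(arr: np.ndarray, flip_idx: np.ndarray) -> np.ndarray:
        # a state-independent set is invariant under relabelling states
        if arr.shape[0] == 1:
            return arr
        return np.take(arr, flip_idx, axis=0)

    def post_image(self, x: SymbolicSet) -> SymbolicSet:
        """All successors (within the colour constraint) of members of x."""
        u = self.universe
        arr = x.array & self.colours.array
        out = arr & self.self_loop
        for i in range(u.n):
            diff = self.update[i] ^ u.lift_state(u.state_bits[i])
            cond = arr & diff  # transitions via variable i start here
            out = out | self._take_flip(cond, u.flip[i])
        return SymbolicSet(u, out)

    def pre_image(self, x: SymbolicSet) -> SymbolicSet:
        """All predecessors (within the colour constraint) of members of x."""
        u = self.universe
        arr = x.array & self.colours.array
        out = arr & self.self_loop
        for i in range(u.n):
            diff = self.update[i] ^ u.lift_state(u.state_bits[i])
            out = out | (self._take_flip(arr, u.flip[i]) & diff)
        return SymbolicSet(u, out & self.colours.array)

    # -- decoding helpers -------------------------------------------------

    def slice_network(self, colour_index: int) -> P.BooleanNetwork:
        """The concrete network encoded by one colour (by update tables)."""
        u = self.universe
        tables = []
        for i in range(u.n):
            full = np.broadcast_to(self.update[i],
                                   (u.S,) + self.update[i].shape[1:])
            flat = full.reshape(u.S, -1)
            col = flat[:, 0] if flat.shape[1] == 1 else flat[:, colour_index]
            tables.append(tuple(int(b) for b in col))
        return P.BooleanNetwork(u.variables, tuple(tables))


def build_coloured_stg(eliminated: P.PSBN, colours: Optional[SymbolicSet],
                       universe: SymbolicUniverse) -> ColouredSTG:
    return ColouredSTG(universe, eliminated, colours)
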
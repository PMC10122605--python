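"""Shared fixtures and small random generators for the test suite."""

from __future__ import annotations

import random
from typing import List, Sequence

import pytest

from bnsketch import psbn as P
from bnsketch import hctl as H
from bnsketch import datagen as D


@pytest.fixture
def v3():
    return ("v1", "v2", "v3")


@pytest.fixture
def running_sketch():
    return D.running_example_sketch()


@pytest.fixture
def running_network():
    return D.running_example_network()


def network_from_exprs(variables: Sequence[str], texts: Sequence[str]) -> P.BooleanNetwork:
    exprs = tuple(P.parse_expression(t, variables) for t in texts)
    return P.specialize(P.PSBN(tuple(variables), exprs), {})


def random_expression(rng: random.Random, variables: Sequence[str],
                      symbols: List[P.FunctionSymbol], depth: int) -> P.Expr:
    """A random partially specified expression (used for round-trip and
    elimination soundness checks)."""
    if depth == 0:
        roll = rng.random()
        if roll < 0.2:
            return P.Const(rng.randint(0, 1))
        i = rng.randrange(len(variables))
        return P.Var(variables[i], i)
    roll = rng.random()
    if roll < 0.15 and symbols:
        sym = rng.choice(symbols)
        args = tuple(random_expression(rng, variables, symbols, depth - 1)
                     for _ in range(sym.arity))
        return P.App(sym, args)
    if roll < 0.3:
        return P.Not(random_expression(rng, variables, symbols, depth - 1))
    node = rng.choice([P.And, P.Or, P.Imp, P.Iff, P.Xor])
    return node(random_expression(rng, variables, symbols, depth - 1),
                random_expression(rng, variables, symbols, depth - 1))


def random_closed_hctl(rng: random.Random, variables: Sequence[str],
                       depth: int = 4, max_quantifiers: int = 2) -> H.HCTLFormula:
    """A random closed HCTL formula with a bounded quantifier budget."""

    def go(depth: int, scope: List[str], budget: int) -> H.HCTLFormula:
        if depth == 0:
            roll = rng.random()
            if roll < 0.2:
                return H.HConst(rng.randint(0, 1))
            if roll < 0.4 and scope:
                return H.HSVar(rng.choice(scope))
            return H.HProp(rng.choice(list(variables)))
        roll = rng.random()
        if roll < 0.18 and budget > 0:
            name = f"q{max_quantifiers - budget}"
            kind = rng.choice(["bind", "exists", "forall"])
            body = go(depth - 1, scope + [name], budget - 1)
            if kind == "bind":
                return H.HBind(name, body)
            if kind == "exists":
                return H.HExists(name, body)
            return H.HForall(name, body)
        if roll < 0.25 and scope:
            return H.HAt(rng.choice(scope), go(depth - 1, scope, budget))
        if roll < 0.45:
            node = rng.choice([H.HEX, H.HEF, H.HEG, H.HAX, H.HAF, H.HAG])
            return node(go(depth - 1, scope, budget))
        if roll < 0.55:
            node = rng.choice([H.HEU, H.HAU])
            return node(go(depth - 1, scope, budget), go(depth - 1, scope, budget))
        if roll < 0.65:
            return H.HNot(go(depth - 1, scope, budget))
        node = rng.choice([H.HAnd, H.HOr, H.HImp, H.HIff])
        return node(go(depth - 1, scope, budget), go(depth - 1, scope, budget))

    return go(depth, [], max_quantifiers)


def random_network(rng: random.Random, variables: Sequence[str]) -> P.BooleanNetwork:
    n = len(variables)
    tables = tuple(tuple(rng.randint(0, 1) for _ in range(1 << n))
                   for _ in range(n))
    return P.BooleanNetwork(tuple(variables), tables)
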
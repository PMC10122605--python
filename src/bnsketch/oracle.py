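"""Explicit-state reference implementation.

Everything here is deliberately naive: states are enumerated one by one,
the state-transition graph is an explicit :mod:`networkx` digraph,
attractors come from the condensation, HCTL is evaluated by structural
recursion with explicit environments, and inference is brute-force
enumeration of all interpretations.  None of the symbolic machinery of
:mod:`bnsketch.engine` / :mod:`bnsketch.mc` is used, so the two routes can
serve as independent checks of one another.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import networkx as nx

from . import hctl as H
from . import psbn as P
from . import sketch as SK

__all__ = ["explicit_stg", "explicit_attractors", "explicit_hctl",
           "property_holds_on_table", "oracle_infer"]

MAX_EXPLICIT_N = 20
MAX_ORACLE_COLOURS = 1 << 16


def explicit_stg(network: P.BooleanNetwork) -> nx.DiGraph:
    """The asynchronous STG with states as row indices.

    One variable flips per transition; fixed points carry a self-loop so
    that every state has at least one successor.
    """
    n = network.n
    if n > MAX_EXPLICIT_N:
        raise ValueError(f"{n} variables exceed the explicit-state limit")
    g = nx.DiGraph()
    g.add_nodes_from(range(1 << n))
    for s in range(1 << n):
        bits = P.index_state(s, n)
        image = network.update(bits)
        moved = False
        for i in range(n):
            if image[i] != bits[i]:
                g.add_edge(s, s ^ (1 << (n - 1 - i)))
                moved = True
        if not moved:
            g.add_edge(s, s)
    return g


def explicit_attractors(g: nx.DiGraph) -> List[Tuple[FrozenSet[int], str]]:
    """Bottom strongly connected components, tagged by shape.

    ``fixed_point`` for singletons, ``cyclic`` when the component is a
    single cycle, ``complex`` otherwise.
    """
    cond = nx.condensation(g)
    out: List[Tuple[FrozenSet[int], str]] = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = frozenset(cond.nodes[comp_id]["members"])
            if len(members) == 1:
                kind = "fixed_point"
            else:
                sub = g.subgraph(members)
                kind = "cyclic" if all(sub.out_degree(s) == 1 for s in members) \
                    else "complex"
            out.append((members, kind))
    out.sort(key=lambda pair: min(pair[0]))
    return out


def explicit_hctl(phi: H.HCTLFormula, g: nx.DiGraph,
                  env: Mapping[str, int] | None = None) -> Set[int]:
    """States satisfying ``phi`` under an environment of state variables.

    Quantifiers iterate over all states; the environment maps state-variable
    names to state indices.
    """
    env = dict(env or {})
    states = list(g.nodes)
    n_vars = (len(states) - 1).bit_length()

    free = H.free_svars(phi)
    if not free <= set(env):
        raise KeyError(f"unbound state variables: {sorted(free - set(env))}")

    def sat(f: H.HCTLFormula, env: Dict[str, int]) -> Set[int]:
        if isinstance(f, H.HConst):
            return set(states) if f.value else set()
        if isinstance(f, H.HProp):
            i = g.graph["variables"].index(f.name) if "variables" in g.graph else None
            if i is None:
                raise KeyError(
                    "the explicit STG does not carry variable names; "
                    "set g.graph['variables']")
            bit = 1 << (n_vars - 1 - i)
            return {s for s in states if s & bit}
        if isinstance(f, H.HSVar):
            return {env[f.name]}
        if isinstance(f, H.HNot):
            return set(states) - sat(f.arg, env)
        if isinstance(f, H.HAnd):
            return sat(f.left, env) & sat(f.right, env)
        if isinstance(f, H.HOr):
            return sat(f.left, env) | sat(f.right, env)
        if isinstance(f, H.HImp):
            return (set(states) - sat(f.left, env)) | sat(f.right, env)
        if isinstance(f, H.HIff):
            a, b = sat(f.left, env), sat(f.right, env)
            return (a & b) | (set(states) - a - b)
        if isinstance(f, H.HEX):
            target = sat(f.arg, env)
            return {s for s in states if any(t in target for t in g.successors(s))}
        if isinstance(f, H.HAX):
            target = sat(f.arg, env)
            return {s for s in states if all(t in target for t in g.successors(s))}
        if isinstance(f, H.HEF):
            return sat(H.HEU(H.HConst(1), f.arg), env)
        if isinstance(f, H.HAF):
            return sat(H.HAU(H.HConst(1), f.arg), env)
        if isinstance(f, H.HEG):
            return set(states) - sat(H.HAU(H.HConst(1), H.HNot(f.arg)), env)
        if isinstance(f, H.HAG):
            return set(states) - sat(H.HEU(H.HConst(1), H.HNot(f.arg)), env)
        if isinstance(f, H.HEU):
            hold, z = sat(f.left, env), sat(f.right, env)
            changed = True
            while changed:
                changed = False
                for s in states:
                    if s not in z and s in hold and \
                            any(t in z for t in g.successors(s)):
                        z.add(s)
                        changed = True
            return z
        if isinstance(f, H.HAU):
            hold, z = sat(f.left, env), sat(f.right, env)
            changed = True
            while changed:
                changed = False
                for s in states:
                    if s not in z and s in hold and \
                            all(t in z for t in g.successors(s)):
                        z.add(s)
                        changed = True
            return z
        if isinstance(f, H.HAt):
            anchor = env.get(f.var)
            if anchor is None:
                raise KeyError(f"unbound state variable {f.var!r}")
            return set(states) if anchor in sat(f.arg, env) else set()
        if isinstance(f, H.HBind):
            out = set()
            for s in states:
                inner = dict(env)
                inner[f.var] = s
                if s in sat(f.arg, inner):
                    out.add(s)
            return out
        if isinstance(f, H.HExists):
            out: Set[int] = set()
            for w in states:
                inner = dict(env)
                inner[f.var] = w
                out |= sat(f.arg, inner)
                if len(out) == len(states):
                    break
            return out
        if isinstance(f, H.HForall):
            out = set(states)
            for w in states:
                inner = dict(env)
                inner[f.var] = w
                out &= sat(f.arg, inner)
                if not out:
                    break
            return out
        raise TypeError(f"not an HCTL formula: {f!r}")

    return sat(phi, env)


def labelled_stg(network: P.BooleanNetwork) -> nx.DiGraph:
    """Explicit STG annotated with the variable ordering for propositions."""
    g = explicit_stg(network)
    g.graph["variables"] = list(network.variables)
    return g


# ---------------------------------------------------------------------------
# Properties on concrete truth tables (independent of the symbolic encoding)
# ---------------------------------------------------------------------------

def property_holds_on_table(prop: SK.FunctionProperty, table: Sequence[int],
                            variables: Sequence[str]) -> bool:
    """Brute-force evaluation of a function property on one update table."""
    n = len(variables)
    if len(table) != 1 << n:
        raise ValueError("table length must be 2**n")

    def pairs(i: int):
        bit = 1 << (n - 1 - i)
        for row in range(1 << n):
            if not row & bit:
                yield table[row], table[row | bit]

    def go(p: SK.FunctionProperty) -> bool:
        if isinstance(p, SK.Essential):
            i = variables.index(p.var)
            return any(a != b for a, b in pairs(i))
        if isinstance(p, SK.Positive):
            i = variables.index(p.var)
            return all(a <= b for a, b in pairs(i))
        if isinstance(p, SK.Negative):
            i = variables.index(p.var)
            return all(a >= b for a, b in pairs(i))
        if isinstance(p, SK.Canalizing):
            i = variables.index(p.var)
            bit = 1 << (n - 1 - i)
            return all(table[row] == p.out_value for row in range(1 << n)
                       if bool(row & bit) == bool(p.in_value))
        if isinstance(p, SK.Veto):
            return go(SK.Canalizing(p.var, p.sign, 0))
        if isinstance(p, SK.PNot):
            return not go(p.arg)
        if isinstance(p, SK.PAnd):
            return go(p.left) and go(p.right)
        if isinstance(p, SK.POr):
            return go(p.left) or go(p.right)
        if isinstance(p, SK.PImp):
            return (not go(p.left)) or go(p.right)
        raise TypeError(f"not a function property: {p!r}")

    return go(prop)


# ---------------------------------------------------------------------------
# Brute-force inference
# ---------------------------------------------------------------------------

def _table_deps(table: Sequence[int], n: int) -> Set[int]:
    deps = set()
    for i in range(n):
        bit = 1 << (n - 1 - i)
        for row in range(1 << n):
            if not row & bit and table[row] != table[row | bit]:
                deps.add(i)
                break
    return deps


def oracle_infer(sketch: SK.Sketch, mode: str = "all_states"
                 ) -> List[P.BooleanNetwork]:
    """Brute force: enumerate every interpretation and filter by definition.

    Returns the semantically distinct consistent networks, ordered by their
    concatenated truth tables.
    """
    symbols = sketch.psbn.symbols()
    total = 1
    for sym in symbols.values():
        total *= 1 << (1 << sym.arity)
        if total > MAX_ORACLE_COLOURS:
            raise ValueError("interpretation space too large for the oracle")

    names = list(symbols)
    variables = list(sketch.variables)
    n = len(variables)
    preds = {v: set(sketch.ig.predecessors(v)) for v in variables}

    survivors: Dict[Tuple, P.BooleanNetwork] = {}
    for tables in itertools.product(
            *(P.all_tables(symbols[name].arity) for name in names)):
        interp = dict(zip(names, tables))
        network = P.specialize(sketch.psbn, interp)
        # influence-graph consistency of the *actual* dependencies
        ok = True
        for i, v in enumerate(variables):
            deps = _table_deps(network.tables[i], n)
            if not {variables[j] for j in deps} <= preds[v]:
                ok = False
                break
        if not ok:
            continue
        if not all(property_holds_on_table(item.property,
                                           network.tables[item.target], variables)
                   for item in sketch.ufp):
            continue
        if sketch.dynamic:
            g = labelled_stg(network)
            all_states = set(g.nodes)
            good = True
            for phi in sketch.dynamic:
                sat = explicit_hctl(phi, g)
                if mode == "all_states":
                    if sat != all_states:
                        good = False
                        break
                elif not sat:
                    good = False
                    break
            if not good:
                continue
        survivors.setdefault(network.tables, network)
    return [survivors[k] for k in sorted(survivors)]
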
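"""Encoding binarized observations as HCTL, and synthetic test sketches.

Binarized measurements enter the inference as dynamic properties: a
steady-state observation asserts the existence of an attractor (or fixed
point) containing a state matching the observed values, a time series
asserts a chain of reachable states matching the successive measurements.
Variables that were not measured simply contribute no literal, so partial
observations are supported.

The default steady-state anchor is attractor membership, not a fixed
point: when unmeasured variables keep oscillating, an apparent steady
state can correspond to a cyclic or complex attractor.

For testing, :func:`random_sketch` manufactures a ground-truth network,
then degrades it into a sketch (hide update functions behind fresh
symbols, keep only monotonicity knowledge, sample observations from the
true attractors) whose candidate set provably contains the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from . import hctl as H
from . import psbn as P
from . import sketch as SK
from . import oracle as O

__all__ = [
    "ObservationTable", "GroundTruthBundle",
    "encode_steady_state", "encode_time_series", "prohibit_other_attractors",
    "running_example_sketch", "running_example_observations", "random_sketch",
]

ObservationKind = Literal["steady_state", "time_series"]

#: value used for an unmeasured variable in an observation row
NA = None


@dataclass(frozen=True)
class ObservationTable:
    """Rows of partial states; time-series rows are in temporal order."""

    variables: Tuple[str, ...]
    rows: Tuple[Tuple[str, Tuple[Optional[int], ...]], ...]
    kind: ObservationKind = "steady_state"

    def __post_init__(self) -> None:
        for name, values in self.rows:
            if len(values) != len(self.variables):
                raise ValueError(f"row {name!r} has wrong width")
            for v in values:
                if v not in (0, 1, None):
                    raise ValueError(f"row {name!r} contains {v!r}; use 0/1/None")


def _observation_conjunction(variables: Sequence[str],
                             values: Sequence[Optional[int]]) -> H.HCTLFormula:
    literals: List[H.HCTLFormula] = []
    for var, val in zip(variables, values):
        if val is None:
            continue
        literals.append(H.HProp(var) if val else H.HNot(H.HProp(var)))
    if not literals:
        raise ValueError("observation row has no measured variables")
    out = literals[0]
    for lit in literals[1:]:
        out = H.HAnd(out, lit)
    return out


def _anchor(mode: str, var: str) -> H.HCTLFormula:
    if mode == "attractor":
        return H.HBind(var, H.HAG(H.HEF(H.HSVar(var))))
    if mode == "fixed_point":
        return H.HBind(var, H.HAX(H.HSVar(var)))
    raise ValueError(f"unknown steady-state mode {mode!r}")


def encode_steady_state(table: ObservationTable,
                        mode: str = "attractor") -> List[H.HCTLFormula]:
    """One closed formula per row: some attractor (or fixed point) contains
    a state matching the observed values."""
    if table.kind != "steady_state":
        raise ValueError("table does not hold steady-state observations")
    formulas = []
    for name, values in table.rows:
        conj = _observation_conjunction(table.variables, values)
        body = H.HAnd(conj, _anchor(mode, "y"))
        formulas.append(H.HExists("x", H.HAt("x", body)))
    return formulas


def encode_time_series(table: ObservationTable,
                       end_in_attractor: bool = False) -> H.HCTLFormula:
    """Nested reachability through the measurements, in order.

    ``3{x}: @{x}: (d1 & EF (d2 & EF (... dk)))`` with an optional attractor
    anchor conjoined to the last measurement.
    """
    if table.kind != "time_series":
        raise ValueError("table does not hold time-series observations")
    if len(table.rows) < 2:
        raise ValueError("a time series needs at least two measurements")
    conjs = [_observation_conjunction(table.variables, values)
             for _, values in table.rows]
    body = conjs[-1]
    if end_in_attractor:
        body = H.HAnd(body, _anchor("attractor", "y"))
    for conj in reversed(conjs[:-1]):
        body = H.HAnd(conj, H.HEF(body))
    return H.HExists("x", H.HAt("x", body))


def prohibit_other_attractors(variables: Sequence[str],
                              patterns: Sequence[Sequence[Optional[int]]]
                              ) -> H.HCTLFormula:
    """Every attractor state matches one of the given partial states.

    ``V{x}: @{x}: ((!{y}: AG EF {y}) => (p1 | p2 | ...))``.
    """
    if not patterns:
        raise ValueError("at least one allowed attractor pattern is required")
    disj: Optional[H.HCTLFormula] = None
    for pat in patterns:
        conj = _observation_conjunction(variables, pat)
        disj = conj if disj is None else H.HOr(disj, conj)
    body = H.HImp(_anchor("attractor", "y"), disj)
    return H.HForall("x", H.HAt("x", body))


# ---------------------------------------------------------------------------
# The running example
# ---------------------------------------------------------------------------

def running_example_observations() -> ObservationTable:
    """The two binarized steady-state measurements of the running example."""
    return ObservationTable(
        variables=("v1", "v2", "v3"),
        rows=(("1", (0, 0, 1)), ("2", (1, 1, 0))),
        kind="steady_state",
    )


def running_example_sketch(include_shared_basin: bool = True,
                           include_data: bool = True) -> SK.Sketch:
    """The three-variable tutorial sketch.

    Influence graph: v3 regulates v1; v1 regulates v2; v1, v2 and v3 itself
    regulate v3.  PSBN: ``E1 = f(v3)``, ``E2 = g(v1)``,
    ``E3 = v3 | h(v1, v2)`` with uninterpreted symbols f(1), g(1), h(2).
    Function properties force f to be the negation (v3 essential and
    negatively monotone in E1) and narrow h to four functions (v1, v2
    essential in E3, v1 positive): v1|v2, v1&v2, v1|!v2, v1&!v2.  Optional
    dynamic properties: a shared weak basin of two attractors, and the two
    steady-state observations (0,0,1) and (1,1,0).

    The fully refined sketch leaves a single candidate: g = v1 and
    h = v1 & !v2, i.e. the network F1 = !v3, F2 = v1,
    F3 = v3 | (v1 & !v2), whose two fixed points are exactly the observed
    states.
    """
    variables = ("v1", "v2", "v3")
    ig = SK.InfluenceGraph(
        variables=variables,
        edges=frozenset([("v3", "v1"), ("v1", "v2"), ("v1", "v3"),
                         ("v2", "v3"), ("v3", "v3")]),
    )
    symbols = {
        "f": P.FunctionSymbol("f", 1),
        "g": P.FunctionSymbol("g", 1),
        "h": P.FunctionSymbol("h", 2),
    }
    psbn = P.PSBN(variables, (
        P.parse_expression("f(v3)", variables, symbols),
        P.parse_expression("g(v1)", variables, symbols),
        P.parse_expression("v3 | h(v1, v2)", variables, symbols),
    ))
    ufp = (
        SK.UFPItem(0, SK.PAnd(SK.Essential("v3"), SK.Negative("v3"))),
        SK.UFPItem(2, SK.PAnd(SK.PAnd(SK.Essential("v1"), SK.Essential("v2")),
                              SK.Positive("v1"))),
    )
    dynamic: List[H.HCTLFormula] = []
    if include_shared_basin:
        dynamic.append(H.shared_basin_formula())
    if include_data:
        dynamic.extend(encode_steady_state(running_example_observations()))
    return SK.Sketch(ig, psbn, ufp, tuple(dynamic))


def running_example_network() -> P.BooleanNetwork:
    """The single candidate of the fully refined running example."""
    variables = ("v1", "v2", "v3")
    exprs = (
        P.parse_expression("!v3", variables),
        P.parse_expression("v1", variables),
        P.parse_expression("v3 | (v1 & !v2)", variables),
    )
    return P.specialize(P.PSBN(variables, exprs), {})


# ---------------------------------------------------------------------------
# Random ground-truth bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthBundle:
    """A known network plus a sketch generated from it.

    By construction, the true network is consistent with every component of
    the sketch, so inference must keep it in the candidate set.
    """

    network: P.BooleanNetwork
    sketch: SK.Sketch
    observations: ObservationTable
    params: Dict[str, object] = field(default_factory=dict, compare=False)


def _table_to_expression(table: Sequence[int], regs: Sequence[P.Var]) -> P.Expr:
    """Minterm expansion of a truth table over the given regulator refs."""
    k = len(regs)
    ones = [r for r in range(1 << k) if table[r]]
    if not ones:
        return P.Const(0)
    if len(ones) == 1 << k:
        return P.Const(1)
    terms: List[P.Expr] = []
    for row in ones:
        term: Optional[P.Expr] = None
        for i in range(k):
            bit = (row >> (k - 1 - i)) & 1
            lit: P.Expr = regs[i] if bit else P.Not(regs[i])
            term = lit if term is None else P.And(term, lit)
        terms.append(term if term is not None else P.Const(1))
    out = terms[0]
    for t in terms[1:]:
        out = P.Or(out, t)
    return out


def _monotone(table: Sequence[int], k: int, pos: int, direction: int) -> bool:
    bit = 1 << (k - 1 - pos)
    for row in range(1 << k):
        if not row & bit:
            lo, hi = table[row], table[row | bit]
            if direction > 0 and lo > hi:
                return False
            if direction < 0 and lo < hi:
                return False
    return True


def _essential_in(table: Sequence[int], k: int, pos: int) -> bool:
    bit = 1 << (k - 1 - pos)
    return any(table[row] != table[row | bit]
               for row in range(1 << k) if not row & bit)


def random_sketch(n: int, max_in_degree: int = 2, hidden_fraction: float = 0.5,
                  n_observations: int = 2, seed: int = 0,
                  max_colour_bits: int = 12) -> GroundTruthBundle:
    """Sample a ground-truth network and degrade it into a sketch.

    Each variable receives 1..``max_in_degree`` regulators and a random
    update function of them; the influence graph records exactly those
    regulations.  A ``hidden_fraction`` of the update functions is replaced
    by fresh uninterpreted symbols over the same regulators (subject to a
    budget of ``max_colour_bits`` parameter constants), and for every
    regulator in which a hidden true function is monotone and essential, a
    sign property is emitted.  Observations are states sampled from the
    true attractors, encoded as steady-state properties.

    Deterministic per ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one variable")
    if not 1 <= max_in_degree <= min(n, 3):
        raise ValueError("max_in_degree must be between 1 and min(n, 3)")
    if not 0.0 <= hidden_fraction <= 1.0:
        raise ValueError("hidden_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    variables = tuple(f"v{i + 1}" for i in range(n))

    reg_sets: List[Tuple[int, ...]] = []
    reg_tables: List[Tuple[int, ...]] = []
    edges = set()
    for i in range(n):
        k = int(rng.integers(1, max_in_degree + 1))
        regs = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        table = tuple(int(b) for b in rng.integers(0, 2, size=1 << k))
        reg_sets.append(regs)
        reg_tables.append(table)
        for j in regs:
            edges.add((variables[j], variables[i]))
    ig = SK.InfluenceGraph(variables, frozenset(edges))

    # hide update functions behind symbols, within the parameter budget
    order = rng.permutation(n)
    budget = max_colour_bits
    hidden = set()
    for i in order:
        cost = 1 << len(reg_sets[int(i)])
        if rng.random() < hidden_fraction and cost <= budget:
            hidden.add(int(i))
            budget -= cost

    expressions: List[P.Expr] = []
    ufp: List[SK.UFPItem] = []
    for i in range(n):
        regs = [P.Var(variables[j], j) for j in reg_sets[i]]
        if i in hidden:
            sym = P.FunctionSymbol(f"f_{variables[i]}", len(regs))
            expressions.append(P.App(sym, tuple(regs)))
            k = len(regs)
            for pos, j in enumerate(reg_sets[i]):
                if not _essential_in(reg_tables[i], k, pos):
                    continue
                if _monotone(reg_tables[i], k, pos, +1):
                    ufp.append(SK.UFPItem(i, SK.Positive(variables[j])))
                elif _monotone(reg_tables[i], k, pos, -1):
                    ufp.append(SK.UFPItem(i, SK.Negative(variables[j])))
        else:
            expressions.append(_table_to_expression(reg_tables[i], regs))
    psbn = P.PSBN(variables, tuple(expressions))

    # the true network: expand each regulator-local table to the full space
    tables = []
    for i in range(n):
        regs = reg_sets[i]
        k = len(regs)
        full = []
        for s in range(1 << n):
            bits = P.index_state(s, n)
            row = P.state_index([bits[j] for j in regs])
            full.append(reg_tables[i][row])
        tables.append(tuple(full))
    network = P.BooleanNetwork(variables, tuple(tables))

    # observations: states sampled from the true attractors
    attractor_states = sorted(
        s for members, _ in O.explicit_attractors(O.explicit_stg(network))
        for s in members)
    rows = []
    for r in range(n_observations):
        s = int(attractor_states[int(rng.integers(0, len(attractor_states)))])
        rows.append((str(r + 1), P.index_state(s, n)))
    observations = ObservationTable(variables, tuple(rows), "steady_state")
    dynamic = tuple(encode_steady_state(observations)) if rows else ()

    bundle_sketch = SK.Sketch(ig, psbn, tuple(ufp), dynamic)
    params = {"n": n, "max_in_degree": max_in_degree,
              "hidden_fraction": hidden_fraction,
              "n_observations": n_observations, "seed": seed,
              "hidden_variables": sorted(variables[i] for i in hidden)}
    return GroundTruthBundle(network, bundle_sketch, observations, params)
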
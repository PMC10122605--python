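"""Influence graphs, function properties, the sketch container."""

import itertools
import random

import numpy as np
import pytest

from bnsketch import psbn as P
from bnsketch import sketch as SK
from bnsketch import oracle as O
from bnsketch.engine import SymbolicUniverse


def _ig(variables, edges):
    return SK.InfluenceGraph(tuple(variables), frozenset(edges))


class TestInfluenceGraph:
    def test_syntactic_consistency(self, v3):
        ig = _ig(v3, [("v1", "v3"), ("v2", "v3"), ("v1", "v2"), ("v3", "v1")])
        psbn = P.PSBN(v3, tuple(P.parse_expression(t, v3)
                                for t in ("v3", "v1", "v1 & v2")))
        assert SK.check_ig_consistency(psbn, ig)

    def test_violation_detected(self, v3):
        ig = _ig(v3, [("v1", "v2"), ("v1", "v3")])
        psbn = P.PSBN(v3, tuple(P.parse_expression(t, v3)
                                for t in ("v3", "v1", "v1")))
        assert not SK.check_ig_consistency(psbn, ig)

    def test_fully_unspecified_psbn_is_consistent(self, v3):
        ig = _ig(v3, [("v1", "v2"), ("v2", "v3"), ("v3", "v1")])
        exprs = []
        for i, v in enumerate(v3):
            preds = ig.predecessors(v)
            sym = P.FunctionSymbol(f"u{i}", len(preds))
            idx = {w: j for j, w in enumerate(v3)}
            exprs.append(P.App(sym, tuple(P.Var(p, idx[p]) for p in preds)))
        assert SK.check_ig_consistency(P.PSBN(v3, tuple(exprs)), ig)

    @pytest.mark.parametrize("edges,expected", [
        ([("v1", "v1"), ("v2", "v2")], 16),
        ([], 4),
    ])
    def test_count_closed_form(self, edges, expected):
        assert SK.count_ig_consistent(_ig(("v1", "v2"), edges)) == expected

    def test_count_matches_brute_force(self):
        """The closed form equals counting, per variable, the update tables
        whose actual dependencies stay within the allowed regulators."""
        rng = random.Random(17)
        for _ in range(10):
            n = rng.randint(1, 3)
            vs = tuple(f"v{i+1}" for i in range(n))
            edges = [(a, b) for a in vs for b in vs if rng.random() < 0.5]
            ig = _ig(vs, edges)
            count = 1
            for v in vs:
                allowed = set(ig.predecessors(v))
                count *= sum(
                    1 for table in P.all_tables(n)
                    if {vs[j] for j in P.dep_set(table)} <= allowed)
            assert SK.count_ig_consistent(ig) == count


def _colour_set(expr_text, variables, symbols, prop):
    psbn = P.PSBN(tuple(variables),
                  (P.parse_expression(expr_text, variables, symbols),)
                  + tuple(P.Const(0) for _ in variables[1:]))
    elim, tab = P.eliminate_symbols(psbn)
    u = SymbolicUniverse(psbn.variables, tab.constants)
    vec = SK.evaluate_property(prop, elim.expressions[0], u).colour_vector()
    return vec, tab, elim


class TestPropertyEvaluation:
    def test_negation_forced_on_running_e1(self, v3):
        prop = SK.PAnd(SK.Essential("v3"), SK.Negative("v3"))
        vec, tab, _ = _colour_set("f(v3)", v3, [P.FunctionSymbol("f", 1)], prop)
        surviving = np.flatnonzero(vec)
        assert len(surviving) == 1
        m = len(tab.constants)
        val = {c: (int(surviving[0]) >> (m - 1 - j)) & 1
               for j, c in enumerate(tab.constants)}
        assert P.interpretation_from_constants(tab, val)["f"] == (1, 0)

    def test_four_options_on_running_e3(self, v3):
        prop = SK.PAnd(SK.PAnd(SK.Essential("v1"), SK.Essential("v2")),
                       SK.Positive("v1"))
        vec, tab, _ = _colour_set("v3 | h(v1, v2)", v3,
                                  [P.FunctionSymbol("h", 2)], prop)
        surviving = np.flatnonzero(vec)
        m = len(tab.constants)
        options = set()
        for c in surviving:
            val = {name: (int(c) >> (m - 1 - j)) & 1
                   for j, name in enumerate(tab.constants)}
            options.add(P.interpretation_from_constants(tab, val)["h"])
        assert options == {(0, 1, 1, 1), (0, 0, 0, 1), (1, 0, 1, 1), (0, 0, 1, 0)}

    def test_tautological_property_keeps_full_space(self, v3):
        vec, _, _ = _colour_set("v1", v3, [], SK.Positive("v1"))
        assert vec.all()

    def test_contradictory_properties_empty(self, v3):
        prop = SK.PAnd(SK.PAnd(SK.Positive("v1"), SK.Negative("v1")),
                       SK.Essential("v1"))
        vec, _, _ = _colour_set("f(v1)", v3, [P.FunctionSymbol("f", 1)], prop)
        assert not vec.any()

    def test_atoms_match_brute_force(self, v3):
        """Symbolic property evaluation equals enumerating every valuation
        and checking the property on the resulting truth table."""
        rng = random.Random(29)
        symbols = [P.FunctionSymbol("f", 1), P.FunctionSymbol("g", 0)]
        atoms = [SK.Essential, SK.Positive, SK.Negative]
        for trial in range(40):
            from conftest import random_expression
            e = random_expression(rng, v3, symbols, rng.randint(1, 3))
            psbn = P.PSBN(v3, (e, P.Const(0), P.Const(0)))
            elim, tab = P.eliminate_symbols(psbn)
            consts = tab.constants
            if len(consts) > 10:
                continue
            var = rng.choice(list(v3))
            atom = rng.choice(atoms)(var)
            if rng.random() < 0.3:
                atom = SK.PNot(atom)
            if rng.random() < 0.3:
                atom = SK.POr(atom, SK.Canalizing(rng.choice(list(v3)),
                                                  rng.randint(0, 1),
                                                  rng.randint(0, 1)))
            u = SymbolicUniverse(psbn.variables, consts)
            vec = SK.evaluate_property(atom, elim.expressions[0], u).colour_vector()
            m = len(consts)
            for c in range(1 << m):
                val = {name: (c >> (m - 1 - j)) & 1
                       for j, name in enumerate(consts)}
                interp = P.interpretation_from_constants(tab, val)
                table = tuple(P.evaluate(e, P.index_state(s, 3), interp)
                              for s in range(8))
                assert bool(vec[c]) == O.property_holds_on_table(atom, table, v3)

    def test_ufp_intersection_is_monotone(self, v3):
        symbols = [P.FunctionSymbol("f", 1), P.FunctionSymbol("h", 2)]
        psbn = P.PSBN(v3, (
            P.parse_expression("f(v3)", v3, symbols),
            P.parse_expression("v1", v3, symbols),
            P.parse_expression("h(v1, v2)", v3, symbols),
        ))
        elim, tab = P.eliminate_symbols(psbn)
        u = SymbolicUniverse(psbn.variables, tab.constants)
        items = [SK.UFPItem(0, SK.Essential("v3")),
                 SK.UFPItem(2, SK.Positive("v1")),
                 SK.UFPItem(2, SK.Essential("v2"))]
        prev = SK.ufp_constraint([], elim, u).colour_vector()
        assert prev.all()  # empty property set keeps the full space
        for k in range(1, len(items) + 1):
            vec = SK.ufp_constraint(items[:k], elim, u).colour_vector()
            assert not (vec & ~prev).any()  # never grows
            prev = vec


class TestPropertySyntax:
    def test_parse_format_round_trip(self, v3):
        texts = ["essential(v1)", "positive(v2) & !negative(v3)",
                 "canalizing(v1, 0, 1) | veto(v2, 1)",
                 "essential(v1) => positive(v1)"]
        for text in texts:
            p = SK.parse_property(text, v3)
            assert SK.parse_property(SK.format_property(p), v3) == p

    def test_unknown_variable_rejected(self, v3):
        with pytest.raises(P.ExprParseError):
            SK.parse_property("essential(v9)", v3)


class TestSketchContainer:
    def test_rejects_open_dynamic_formula(self, v3):
        from bnsketch import hctl as H
        ig = _ig(v3, [("v1", "v1")])
        psbn = P.PSBN(v3, (P.parse_expression("v1", v3),) * 1
                      + (P.Const(0), P.Const(0)))
        with pytest.raises(ValueError, match="free state variables"):
            SK.Sketch(ig, psbn, (), (H.HEF(H.HSVar("x")),))

    def test_rejects_mismatched_variables(self, v3):
        ig = _ig(("a", "b"), [])
        psbn = P.PSBN(v3, (P.Const(0), P.Const(0), P.Const(0)))
        with pytest.raises(ValueError):
            SK.Sketch(ig, psbn)
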
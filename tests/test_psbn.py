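"""Expressions, interpretations, dependency analysis, symbol elimination."""

import itertools
import random

import pytest

from bnsketch import psbn as P

F1 = P.FunctionSymbol("f", 1)
G0 = P.FunctionSymbol("g", 0)
H2 = P.FunctionSymbol("h", 2)


class TestParser:
    def test_apply_inside_boolean_structure(self, v3):
        e = P.parse_expression("v2 & !f(v3)", v3, [F1])
        assert e == P.And(P.Var("v2", 1),
                          P.Not(P.App(F1, (P.Var("v3", 2),))))

    def test_zero_arity_symbol_written_bare(self, v3):
        assert P.parse_expression("g", v3, [G0]) == P.App(G0, ())
        assert P.parse_expression("g()", v3, [G0]) == P.App(G0, ())

    def test_arity_mismatch_rejected(self, v3):
        with pytest.raises(P.ExprParseError):
            P.parse_expression("f(v1, v2)", v3, [F1])

    def test_undeclared_identifier_rejected(self, v3):
        with pytest.raises(P.ExprParseError, match="undeclared"):
            P.parse_expression("v1 & bogus", v3)

    def test_trailing_garbage_rejected(self, v3):
        with pytest.raises(P.ExprParseError, match="trailing"):
            P.parse_expression("v1 v2", v3)

    @pytest.mark.parametrize("text,state,value", [
        ("v1 | v2 & v3", (0, 0, 1), 0),   # & binds tighter than |
        ("v1 | v2 & v3", (0, 1, 1), 1),
        ("v1 ^ v2 | v3", (1, 0, 1), 0),   # | binds tighter than ^
        ("v1 => v2 => v3", (1, 0, 0), 1),  # => right-associative
        ("v1 <=> v2 => v3", (0, 1, 0), 1),  # => binds tighter than <=>
    ])
    def test_precedence(self, v3, text, state, value):
        e = P.parse_expression(text, v3)
        assert P.evaluate(e, state, {}) == value

    def test_print_parse_round_trip_random(self, v3):
        from conftest import random_expression
        rng = random.Random(7)
        symbols = [F1, G0, H2]
        for _ in range(200):
            e = random_expression(rng, v3, symbols, rng.randint(0, 4))
            text = P.format_expression(e)
            again = P.parse_expression(text, v3, symbols)
            for state in itertools.product((0, 1), repeat=3):
                interp = {"f": (0, 1), "g": (1,), "h": (0, 1, 1, 0)}
                assert P.evaluate(e, state, interp) == \
                    P.evaluate(again, state, interp)


class TestSemantics:
    def test_syntactic_inputs(self, v3):
        e = P.parse_expression("v2 & f(v3)", v3, [F1])
        assert P.syntactic_inputs(e) == {"v2", "v3"}
        assert P.syntactic_inputs(P.Const(1)) == frozenset()
        dup = P.App(H2, (P.Var("v1", 0), P.Var("v1", 0)))
        assert P.syntactic_inputs(dup) == {"v1"}

    def test_evaluate_plain_and_applied(self, v3):
        e = P.parse_expression("v1 & !v2", v3)
        assert P.evaluate(e, (1, 1, 0), {}) == 0
        h = P.parse_expression("h(v1, v2)", v3, [H2])
        # h = v1 & !v2 as a truth table over (arg1, arg2)
        assert P.evaluate(h, (1, 0, 0), {"h": (0, 0, 1, 0)}) == 1
        g = P.parse_expression("g", v3, [G0])
        assert P.evaluate(g, (0, 0, 0), {"g": (1,)}) == 1

    def test_evaluate_missing_symbol(self, v3):
        g = P.parse_expression("g", v3, [G0])
        with pytest.raises(KeyError):
            P.evaluate(g, (0, 0, 0), {})

    def test_desugaring_preserves_semantics(self, v3):
        from conftest import random_expression
        rng = random.Random(11)
        for _ in range(200):
            e = random_expression(rng, v3, [F1, H2], rng.randint(1, 4))
            core = P.desugar_expr(e)
            assert not _has_sugar(core)
            interp = {"f": (1, 0), "h": (0, 1, 0, 1)}
            for state in itertools.product((0, 1), repeat=3):
                assert P.evaluate(e, state, interp) == \
                    P.evaluate(core, state, interp)

    def test_row_order_convention(self, v3):
        """evaluate(f(args)) reads the interpretation table at the row index
        of the evaluated arguments, first argument most significant."""
        h = P.parse_expression("h(v1, v2)", v3, [H2])
        table = (0, 1, 1, 0)
        for state in itertools.product((0, 1), repeat=3):
            row = (state[0] << 1) | state[1]
            assert P.evaluate(h, state, {"h": table}) == table[row]


def _has_sugar(e):
    if isinstance(e, (P.Or, P.Imp, P.Iff, P.Xor)):
        return True
    if isinstance(e, P.Not):
        return _has_sugar(e.arg)
    if isinstance(e, P.And):
        return _has_sugar(e.left) or _has_sugar(e.right)
    if isinstance(e, P.App):
        return any(_has_sugar(a) for a in e.args)
    return False


class TestNetworks:
    def test_specialize_running_psbn(self, v3):
        symbols = [F1, P.FunctionSymbol("g", 1), H2]
        psbn = P.PSBN(v3, (
            P.parse_expression("f(v3)", v3, symbols),
            P.parse_expression("g(v1)", v3, symbols),
            P.parse_expression("v3 | h(v1, v2)", v3, symbols),
        ))
        interp = {"f": (1, 0), "g": (0, 1), "h": (0, 0, 1, 0)}
        nw = P.specialize(psbn, interp)
        # F2(x) = x1 for every state
        for s in range(8):
            state = P.index_state(s, 3)
            assert nw.tables[1][s] == state[0]

    def test_specialize_without_symbols_ignores_interpretation(self, v3):
        psbn = P.PSBN(v3, tuple(P.parse_expression(t, v3)
                                for t in ("v1", "!v2", "v1 & v3")))
        assert P.specialize(psbn, {}) == P.specialize(psbn, {"junk": (0, 1)})

    def test_constant_symbol_network(self):
        psbn = P.PSBN(("v1",), (P.App(P.FunctionSymbol("f", 0), ()),))
        nw = P.specialize(psbn, {"f": (0,)})
        assert nw.tables == ((0, 0),)

    @pytest.mark.parametrize("text,expected", [
        ("v2 & !v3", {1, 2}),
        ("0", set()),
        ("v1 ^ v2", {0, 1}),
    ])
    def test_dep_set(self, v3, text, expected):
        table = tuple(P.evaluate(P.parse_expression(text, v3),
                                 P.index_state(s, 3), {}) for s in range(8))
        assert P.dep_set(table) == expected

    def test_dep_set_matches_brute_force_definition(self):
        rng = random.Random(3)
        for _ in range(50):
            n = rng.randint(1, 4)
            table = [rng.randint(0, 1) for _ in range(1 << n)]
            expected = set()
            for j in range(n):
                for s in range(1 << n):
                    bits = list(P.index_state(s, n))
                    hi, lo = list(bits), list(bits)
                    hi[j], lo[j] = 1, 0
                    if table[P.state_index(hi)] != table[P.state_index(lo)]:
                        expected.add(j)
            assert P.dep_set(tuple(table)) == expected

    def test_dep_subset_of_syntactic_inputs(self, v3):
        from conftest import random_expression
        rng = random.Random(5)
        for _ in range(50):
            e = random_expression(rng, v3, [F1], rng.randint(1, 3))
            psbn = P.PSBN(v3, (e, P.Const(0), P.Const(0)))
            for f_table in P.all_tables(1):
                nw = P.specialize(psbn, {"f": f_table})
                deps = {v3[j] for j in P.dep_set(nw.tables[0])}
                assert deps <= P.syntactic_inputs(e)


class TestElimination:
    def test_unary_expansion_semantics(self, v3):
        e = P.parse_expression("f(v3)", v3, [F1])
        psbn = P.PSBN(v3, (e, P.Const(0), P.Const(0)))
        elim, tab = P.eliminate_symbols(psbn)
        assert tab.rows["f"] == ["f_0", "f_1"]
        # for the valuation (c0, c1) = (1, 0), the expansion is !v3
        val = {"f_0": 1, "f_1": 0}
        interp = P.interpretation_from_constants(tab, val)
        assert interp == {"f": (1, 0)}

    def test_zero_arity_symbols_pass_through(self, v3):
        e = P.parse_expression("g & v1", v3, [G0])
        elim, tab = P.eliminate_symbols(P.PSBN(v3, (e, P.Const(0), P.Const(0))))
        assert tab.rows["g"] == ["g"]
        assert elim.expressions[0] == e

    def test_running_example_constant_count(self, v3):
        symbols = [F1, P.FunctionSymbol("g", 1), H2]
        psbn = P.PSBN(v3, (
            P.parse_expression("f(v3)", v3, symbols),
            P.parse_expression("g(v1)", v3, symbols),
            P.parse_expression("v3 | h(v1, v2)", v3, symbols),
        ))
        _, tab = P.eliminate_symbols(psbn)
        assert len(tab.constants) == 2 + 2 + 4

    def test_arity_cap_enforced(self, v3):
        big = P.FunctionSymbol("big", 3)
        e = P.App(big, (P.Var("v1", 0), P.Var("v2", 1), P.Var("v3", 2)))
        psbn = P.PSBN(v3, (e, P.Const(0), P.Const(0)))
        with pytest.raises(ValueError, match="arity"):
            P.eliminate_symbols(psbn, arity_cap=2)

    def test_truth_table_read_off(self):
        """Constant valuations decode to the truth table row by row."""
        vs = ("v1", "v2")
        e = P.parse_expression("h(v1, v2)", vs, [H2])
        psbn = P.PSBN(vs, (e, P.Const(0)))
        _, tab = P.eliminate_symbols(psbn)
        val = {"h_00": 0, "h_01": 0, "h_10": 1, "h_11": 1}
        interp = P.interpretation_from_constants(tab, val)
        assert interp["h"] == (0, 0, 1, 1)  # the projection on argument 1

    def test_all_zero_valuation(self, v3):
        symbols = [F1, H2]
        e = P.parse_expression("f(v1) ^ h(v2, v3)", v3, symbols)
        psbn = P.PSBN(v3, (e, P.Const(0), P.Const(0)))
        _, tab = P.eliminate_symbols(psbn)
        interp = P.interpretation_from_constants(
            tab, {c: 0 for c in tab.constants})
        assert interp == {"f": (0, 0), "h": (0, 0, 0, 0)}

    def test_incomplete_valuation_rejected(self, v3):
        e = P.parse_expression("f(v1)", v3, [F1])
        _, tab = P.eliminate_symbols(P.PSBN(v3, (e, P.Const(0), P.Const(0))))
        with pytest.raises(KeyError):
            P.interpretation_from_constants(tab, {"f_0": 1})

    def test_elimination_soundness_bijection(self):
        """The multiset of specializations over all interpretations equals
        the multiset over all constant valuations of the eliminated PSBN."""
        from conftest import random_expression
        rng = random.Random(13)
        for _ in range(25):
            n = rng.randint(1, 3)
            vs = tuple(f"v{i+1}" for i in range(n))
            symbols = [P.FunctionSymbol("f", rng.randint(0, 2)),
                       P.FunctionSymbol("g", rng.randint(0, 2))]
            exprs = tuple(random_expression(rng, vs, symbols, rng.randint(1, 3))
                          for _ in range(n))
            psbn = P.PSBN(vs, exprs)
            used = psbn.symbols()
            elim, tab = P.eliminate_symbols(psbn)
            if sum(1 << s.arity for s in used.values()) > 8:
                continue
            original = sorted(
                P.specialize(psbn, dict(zip(used, tables))).tables
                for tables in itertools.product(
                    *(P.all_tables(used[name].arity) for name in used)))
            consts = tab.constants
            eliminated = []
            for bits in itertools.product((0, 1), repeat=len(consts)):
                val = dict(zip(consts, bits))
                interp = P.interpretation_from_constants(tab, val)
                eliminated.append(P.specialize(psbn, interp).tables)
                # round trip through the eliminated PSBN agrees state by state
                zero_interp = {c: (val[c],) for c in consts}
                assert P.specialize(elim, zero_interp).tables == eliminated[-1]
            assert original == sorted(eliminated)
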
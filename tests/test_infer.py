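"""The inference pipeline: cascade, counting, decoding, membership."""

import random

import numpy as np
import pytest

import bnsketch as B
from bnsketch import psbn as P
from bnsketch import sketch as SK
from bnsketch import hctl as H
from bnsketch import oracle as O
from bnsketch import datagen as D
from conftest import network_from_exprs


class TestRunningExample:
    def test_cascade_counts(self, running_sketch):
        cand = B.infer(running_sketch)
        by_stage = {st["stage"]: st for st in cand.stages}
        assert by_stage["IG"]["networks"] == 4096
        assert by_stage["IG + PSBN"]["networks"] == 256
        assert by_stage["IG + PSBN + UFP"]["interpretations"] == 16
        assert by_stage["IG + PSBN + UFP + DP[1]"]["interpretations"] == 4
        assert cand.stages[-1]["interpretations"] == 1

    def test_final_candidate_decodes_to_stated_interpretation(self, running_sketch):
        cand = B.infer(running_sketch)
        [(interp, nw)] = B.enumerate_candidates(cand, limit=2)
        assert interp["f"] == (1, 0)          # negation
        assert interp["g"] == (0, 1)          # identity: g = v1
        assert interp["h"] == (0, 0, 1, 0)    # h = v1 & !v2
        assert nw == D.running_example_network()

    def test_membership(self, running_sketch, running_network):
        cand = B.infer(running_sketch)
        assert B.contains(cand, running_network)
        other = network_from_exprs(running_network.variables,
                                   ["!v3", "!v1", "v3 | (v1 & !v2)"])
        assert not B.contains(cand, other)


class TestRejections:
    def test_ig_violation(self, v3):
        ig = SK.InfluenceGraph(v3, frozenset([("v1", "v2")]))
        psbn = P.PSBN(v3, (P.parse_expression("v3", v3), P.Const(0), P.Const(0)))
        with pytest.raises(B.IGViolation):
            B.infer(SK.Sketch(ig, psbn))

    def test_unsat_properties(self, v3):
        ig = SK.InfluenceGraph(v3, frozenset([("v1", "v1")]))
        psbn = P.PSBN(v3, (
            P.parse_expression("f(v1)", v3, [P.FunctionSymbol("f", 1)]),
            P.Const(0), P.Const(0)))
        bad = SK.PAnd(SK.PAnd(SK.Positive("v1"), SK.Negative("v1")),
                      SK.Essential("v1"))
        with pytest.raises(B.UnsatProperties):
            B.infer(SK.Sketch(ig, psbn, (SK.UFPItem(0, bad),)))

    def test_unsat_dynamics(self, v3):
        ig = SK.InfluenceGraph(v3, frozenset())
        psbn = P.PSBN(v3, (P.Const(0), P.Const(0), P.Const(0)))
        impossible = H.parse_hctl("3{x}: @{x}: (v1 & ~v1)", v3)
        with pytest.raises(B.UnsatDynamics):
            B.infer(SK.Sketch(ig, psbn, (), (impossible,)))


class TestCounting:
    def test_interpretations_vs_distinct_networks(self):
        """A constant-true expression hides the symbol: two colours, one
        network."""
        vs = ("v1",)
        psbn = P.PSBN(vs, (P.Or(P.App(P.FunctionSymbol("f", 0), ()), P.Const(1)),))
        ig = SK.InfluenceGraph(vs, frozenset())
        cand = B.infer(SK.Sketch(ig, psbn))
        assert B.count_interpretations(cand) == 2
        assert B.count_distinct_networks(cand) == 1

    def test_counts_on_running_example_after_ufp(self):
        sk = D.running_example_sketch(include_shared_basin=False,
                                      include_data=False)
        cand = B.infer(sk)
        assert B.count_interpretations(cand) == 16
        assert B.count_distinct_networks(cand) == 16

    def test_empty_set_counts_zero(self, v3):
        ig = SK.InfluenceGraph(v3, frozenset())
        psbn = P.PSBN(v3, (P.Const(0), P.Const(0), P.Const(0)))
        cand = B.infer(SK.Sketch(ig, psbn))
        cand.colour_vec = np.zeros_like(cand.colour_vec)
        assert B.count_interpretations(cand) == 0
        assert B.count_distinct_networks(cand) == 0
        assert B.enumerate_candidates(cand, 10) == []

    def test_enumerate_limit_zero(self, running_sketch):
        cand = B.infer(running_sketch)
        assert B.enumerate_candidates(cand, 0) == []


class TestAttractorAnalysis:
    def test_fixed_point_included(self, running_sketch):
        cand = B.infer(running_sketch)
        sat, u = B.attractor_states(cand)
        arr = np.broadcast_to(sat.array, (u.S,) + sat.array.shape[1:])
        colour = int(np.flatnonzero(cand.colour_vec)[0])
        states = {s for s in range(u.S)
                  if arr.reshape(u.S, -1)[s, colour]}
        assert 0b110 in states and 0b001 in states

    def test_per_colour_slices_equal_explicit_attractors(self):
        sk = D.running_example_sketch(include_shared_basin=False,
                                      include_data=False)
        cand = B.infer(sk)
        sat, u = B.attractor_states(cand)
        full = np.broadcast_to(
            sat.array, (u.S,) + sat.array.shape[1:]).reshape(u.S, u.C)
        for interp, nw in B.enumerate_candidates(cand, limit=16):
            c = _colour_of(cand, interp)
            expected = set()
            for members, _ in O.explicit_attractors(O.explicit_stg(nw)):
                expected |= members
            assert set(np.flatnonzero(full[:, c])) == expected

    def test_twelve_of_sixteen_have_a_single_attractor(self):
        sk = D.running_example_sketch(include_shared_basin=False,
                                      include_data=False)
        counts = B.attractor_count_per_colour(B.infer(sk))
        histogram = {}
        for k in counts.values():
            histogram[k] = histogram.get(k, 0) + 1
        assert histogram == {1: 12, 2: 4}


def _colour_of(cand, interp):
    bits = []
    for name, rows in cand.symtab.rows.items():
        table = interp[name]
        bits.extend(table)
    return int("".join(str(b) for b in bits), 2)


class TestAgainstOracle:
    def test_random_sketches_agree_with_brute_force(self):
        """Symbolic inference and brute-force enumeration return identical
        sets of networks on random ground-truth sketches."""
        agree = 0
        for seed in range(25):
            bundle = D.random_sketch(3, max_in_degree=2, hidden_fraction=0.8,
                                     n_observations=2, seed=seed,
                                     max_colour_bits=3)
            expected = {nw.tables for nw in O.oracle_infer(bundle.sketch)}
            try:
                cand = B.infer(bundle.sketch)
                got = {nw.tables for _, nw in
                       B.enumerate_candidates(cand, limit=1 << 16, distinct=True)}
            except B.SketchRejected:
                got = set()
            assert got == expected
            agree += 1
        assert agree == 25

    def test_refinement_monotonicity(self):
        """Adding a function property or a dynamic property never increases
        the interpretation count."""
        rng = random.Random(61)
        for seed in range(15):
            bundle = D.random_sketch(3, max_in_degree=2, hidden_fraction=0.9,
                                     n_observations=1, seed=seed,
                                     max_colour_bits=4)
            sk = bundle.sketch
            base = _count(sk)
            # add a random extra property on a hidden expression
            for i, e in enumerate(sk.psbn.expressions):
                inputs = sorted(P.syntactic_inputs(e))
                if not inputs:
                    continue
                var = rng.choice(inputs)
                atom = rng.choice([SK.Essential, SK.Positive, SK.Negative])(var)
                extra = SK.Sketch(sk.ig, sk.psbn, sk.ufp + (SK.UFPItem(i, atom),),
                                  sk.dynamic)
                assert _count(extra) <= base
            extra_phi = H.HExists("w", H.HAt("w", H.HBind("u", H.HAX(H.HSVar("u")))))
            extra = SK.Sketch(sk.ig, sk.psbn, sk.ufp, sk.dynamic + (extra_phi,))
            assert _count(extra) <= base


def _count(sk):
    try:
        return B.count_interpretations(B.infer(sk))
    except B.SketchRejected:
        return 0
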
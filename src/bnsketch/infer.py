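"""The inference procedure: all networks consistent with a sketch.

The pipeline mirrors the sketch components: reject on a syntactic
influence-graph violation, eliminate uninterpreted symbols into parameter
constants, intersect the colour sets of all update-function properties
(reject when contradictory), then model-check every dynamic property over
the coloured STG and keep the colours whose networks satisfy them all
(reject when none survive).  The result is a compact set of colours plus
the decoding tables needed to reconstruct concrete networks and
interpretations.

Two counts are reported throughout: the number of surviving
*interpretations* (colours) and the number of semantically distinct
*networks* (different colours may specialize to the same update tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import hctl as H
from . import psbn as P
from .engine import ColouredSTG, SymbolicSet, SymbolicUniverse, compile_expression
from .mc import SatisfactionMode, check_sketch_formula, model_check
from .sketch import Sketch, check_ig_consistency, count_ig_consistent, ufp_constraint

__all__ = [
    "SketchRejected", "IGViolation", "UnsatProperties", "UnsatDynamics",
    "CandidateSet", "infer", "count_interpretations",
    "count_distinct_networks", "enumerate_candidates", "contains",
    "attractor_states", "attractor_count_per_colour",
]

#: above this many parameter constants, distinct-network counting would
#: materialize all update tables; only colour counts are reported then
MAX_DEDUP_BITS = 20


class SketchRejected(Exception):
    """A sketch component admits no candidate at all."""

    def __init__(self, message: str, stages: Optional[List[dict]] = None):
        super().__init__(message)
        self.stages = stages or []


class IGViolation(SketchRejected):
    """The PSBN mentions a regulator not allowed by the influence graph."""


class UnsatProperties(SketchRejected):
    """The update-function properties are contradictory."""


class UnsatDynamics(SketchRejected):
    """No candidate satisfies all dynamic (HCTL) properties."""


@dataclass
class CandidateSet:
    """Symbolic set of colours plus decoding tables.

    ``colour_vec[c]`` is True when colour ``c`` (read as a binary valuation
    of ``symtab.constants``, first constant most significant) survives every
    sketch component.
    """

    sketch: Sketch
    eliminated: P.PSBN
    symtab: P.SymbolTable
    colour_vec: np.ndarray
    stages: List[dict] = field(default_factory=list)
    mode: SatisfactionMode = "all_states"

    @property
    def m(self) -> int:
        return len(self.symtab.constants)


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _colour_universe(eliminated: P.PSBN, symtab: P.SymbolTable,
                     aux: Sequence[str] = ()) -> SymbolicUniverse:
    return SymbolicUniverse(eliminated.variables, symtab.constants, aux)


def _update_matrix(eliminated: P.PSBN, symtab: P.SymbolTable) -> np.ndarray:
    """Update tables of every colour: Boolean array of shape (n, 2**n, 2**m)."""
    u = _colour_universe(eliminated, symtab)
    rows = []
    for e in eliminated.expressions:
        arr = compile_expression(e, u).array  # (S|1, C|1)
        rows.append(np.broadcast_to(arr, (u.S, u.C)))
    return np.stack(rows)


def _network_signatures(eliminated: P.PSBN, symtab: P.SymbolTable) -> np.ndarray:
    """Per-colour packed update-table signature, shape (2**m, bytes)."""
    mat = _update_matrix(eliminated, symtab)  # (n, S, C)
    n, S, C = mat.shape
    flat = mat.reshape(n * S, C)
    return np.packbits(flat, axis=0).T.copy()


def _valuation_of_colour(symtab: P.SymbolTable, colour_index: int) -> Dict[str, int]:
    consts = symtab.constants
    m = len(consts)
    return {c: (colour_index >> (m - 1 - j)) & 1 for j, c in enumerate(consts)}


def _formula_colours(eliminated: P.PSBN, symtab: P.SymbolTable,
                     colour_vec: np.ndarray, phi: H.HCTLFormula,
                     mode: SatisfactionMode) -> np.ndarray:
    """Colours within ``colour_vec`` whose network satisfies ``phi``."""
    renamed = H.alpha_rename(phi)
    aux = sorted(H.quantified_names(renamed))
    u = _colour_universe(eliminated, symtab, aux)
    colours = SymbolicSet(u, u.lift_colour(colour_vec))
    stg = ColouredSTG(u, eliminated, colours)
    sat = check_sketch_formula(renamed, stg, mode)
    return sat.colour_vector() & colour_vec


# ---------------------------------------------------------------------------
# Counting, decoding, membership
# ---------------------------------------------------------------------------

def count_interpretations(cand: CandidateSet) -> int:
    """Number of surviving colours (= interpretations of the symbols)."""
    return int(np.count_nonzero(cand.colour_vec))


def count_distinct_networks(cand: CandidateSet) -> int:
    """Number of semantically distinct networks among the surviving colours."""
    idx = np.flatnonzero(cand.colour_vec)
    if idx.size == 0:
        return 0
    if cand.m > MAX_DEDUP_BITS:
        raise ValueError(
            f"distinct-network counting not supported above {MAX_DEDUP_BITS} "
            "parameter constants")
    sigs = _network_signatures(cand.eliminated, cand.symtab)[idx]
    return int(np.unique(sigs, axis=0).shape[0])


def enumerate_candidates(cand: CandidateSet, limit: int = 10,
                         distinct: bool = False
                         ) -> List[Tuple[Dict[str, Tuple[int, ...]], P.BooleanNetwork]]:
    """Decode up to ``limit`` candidates, smallest colour valuation first.

    With ``distinct=True``, colours specializing to an already-emitted
    network are skipped.
    """
    if limit < 0:
        raise ValueError("limit must be non-negative")
    out: List[Tuple[Dict[str, Tuple[int, ...]], P.BooleanNetwork]] = []
    seen = set()
    for c in np.flatnonzero(cand.colour_vec):
        if len(out) >= limit:
            break
        valuation = _valuation_of_colour(cand.symtab, int(c))
        interp = P.interpretation_from_constants(cand.symtab, valuation)
        network = P.specialize(cand.sketch.psbn, interp)
        if distinct:
            if network.tables in seen:
                continue
            seen.add(network.tables)
        out.append((interp, network))
    return out


def contains(cand: CandidateSet, network: P.BooleanNetwork) -> bool:
    """Membership: does some surviving colour specialize to ``network``?"""
    if tuple(network.variables) != tuple(cand.sketch.variables):
        raise ValueError("network and sketch variables differ")
    idx = np.flatnonzero(cand.colour_vec)
    if idx.size == 0:
        return False
    sigs = _network_signatures(cand.eliminated, cand.symtab)[idx]
    flat = np.array([b for t in network.tables for b in t], dtype=np.uint8)
    target = np.packbits(flat)
    return bool((sigs == target).all(axis=1).any())


# ---------------------------------------------------------------------------
# Attractor analysis over the whole candidate set
# ---------------------------------------------------------------------------

def attractor_states(cand: CandidateSet) -> Tuple[SymbolicSet, SymbolicUniverse]:
    """(state, colour) pairs where the state lies in an attractor of that
    colour's network, computed by model checking ``!{x}: AG EF {x}``."""
    phi = H.alpha_rename(H.attractor_formula())
    aux = sorted(H.quantified_names(phi))
    u = _colour_universe(cand.eliminated, cand.symtab, aux)
    colours = SymbolicSet(u, u.lift_colour(cand.colour_vec))
    stg = ColouredSTG(u, cand.eliminated, colours)
    sat = model_check(phi, stg)
    return sat, u


def attractor_count_per_colour(cand: CandidateSet) -> Dict[int, int]:
    """Number of attractors of each surviving colour's network.

    The attractor states of one colour split into the attractors themselves
    (mutually unreachable closed sets); each is recovered by closing a seed
    state under the post-image restricted to that colour.
    """
    sat, u = attractor_states(cand)
    stg = ColouredSTG(u, cand.eliminated,
                      SymbolicSet(u, u.lift_colour(cand.colour_vec)))
    counts: Dict[int, int] = {}
    for c in np.flatnonzero(cand.colour_vec):
        col_mask = np.zeros(u.C, dtype=bool)
        col_mask[c] = True
        colour_set = SymbolicSet(u, u.lift_colour(col_mask))
        remaining = sat & colour_set
        k = 0
        while not remaining.is_empty():
            seed_states = remaining.state_vector()
            seed = np.zeros(u.S, dtype=bool)
            seed[int(np.flatnonzero(seed_states)[0])] = True
            component = SymbolicSet(u, u.lift_state(seed)) & colour_set
            while True:
                grown = component | stg.post_image(component)
                if grown.same_as(component):
                    break
                component = grown
            remaining = remaining.minus(component)
            k += 1
        counts[int(c)] = k
    return counts


# ---------------------------------------------------------------------------
# The procedure itself
# ---------------------------------------------------------------------------

def infer(sketch: Sketch, mode: SatisfactionMode = "all_states",
          arity_cap: int = P.DEFAULT_ARITY_CAP,
          stage_networks: bool = True) -> CandidateSet:
    """All networks consistent with the sketch, as a candidate set.

    Raises :class:`IGViolation`, :class:`UnsatProperties` or
    :class:`UnsatDynamics` when a component rules out every candidate.
    Per-stage counts (influence graph alone, plus PSBN, plus function
    properties, plus each dynamic property) are logged on the result.
    """
    stages: List[dict] = []

    if not check_ig_consistency(sketch.psbn, sketch.ig):
        raise IGViolation(
            "the PSBN depends on a regulator not admitted by the influence graph",
            stages)
    stages.append({"stage": "IG", "interpretations": None,
                   "networks": count_ig_consistent(sketch.ig)})

    eliminated, symtab = P.eliminate_symbols(sketch.psbn, arity_cap)
    m = len(symtab.constants)

    def distinct(vec: np.ndarray) -> Optional[int]:
        if not stage_networks or m > MAX_DEDUP_BITS:
            return None
        probe = CandidateSet(sketch, eliminated, symtab, vec)
        return count_distinct_networks(probe)

    full = np.ones(1 << m, dtype=bool)
    stages.append({"stage": "IG + PSBN", "interpretations": 1 << m,
                   "networks": distinct(full)})

    u0 = _colour_universe(eliminated, symtab)
    ufp_vec = ufp_constraint(sketch.ufp, eliminated, u0).colour_vector()
    stages.append({"stage": "IG + PSBN + UFP",
                   "interpretations": int(np.count_nonzero(ufp_vec)),
                   "networks": distinct(ufp_vec)})
    if not ufp_vec.any():
        raise UnsatProperties("the update-function properties are contradictory",
                              stages)

    vec = ufp_vec
    for k, phi in enumerate(sketch.dynamic, start=1):
        vec = _formula_colours(eliminated, symtab, vec, phi, mode)
        stages.append({"stage": f"IG + PSBN + UFP + DP[{k}]",
                       "interpretations": int(np.count_nonzero(vec)),
                       "networks": distinct(vec)})
        if not vec.any():
            raise UnsatDynamics(
                f"no candidate satisfies dynamic property {k} "
                f"({H.format_hctl(phi)})", stages)

    return CandidateSet(sketch, eliminated, symtab, vec, stages, mode)
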
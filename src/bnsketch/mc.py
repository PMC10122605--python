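"""Bottom-up coloured HCTL model checking.

Formulae are evaluated over the coloured asynchronous STG by structural
recursion; every subformula denotes a set of (state, state-variable
valuation, colour) triples.  Temporal operators become fixpoint iterations
of the pre-image operator, the hybrid operators manipulate the auxiliary
state-variable axes:

* ``{x}``        -- the diagonal "current state equals the valuation of x";
* ``!{x}: phi``  -- conjoin that diagonal, then project x away;
* ``@{x}: phi``  -- replace the state axis by the valuation of x
  (the current state becomes irrelevant);
* ``3{x}: phi``  -- existential projection of x's axis.

A colour is *consistent* with a closed formula either when every state of
its STG satisfies it (``all_states``, the default) or when at least one
does (``some_state``).  All formulae generated by this package are
existentially anchored (state-independent), for which the two conventions
coincide; universal properties ("no other attractor exists") need
``all_states``.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np

from . import hctl as H
from .engine import ColouredSTG, SymbolicSet

__all__ = ["model_check", "colours_satisfying", "check_sketch_formula"]

SatisfactionMode = Literal["all_states", "some_state"]


def _jump(r: SymbolicSet, name: str) -> SymbolicSet:
    """Semantics of ``@{x}``: re-anchor evaluation at the state stored in x."""
    u = r.universe
    ax = u.aux_axis(name)
    arr = r.array
    shape = list(arr.shape)
    shape[0] = u.S
    shape[ax] = u.S
    full = np.broadcast_to(arr, shape)
    diag = np.diagonal(full, axis1=0, axis2=ax)  # diagonal axis appended last
    out = np.moveaxis(diag, -1, ax - 1)
    out = np.expand_dims(out, 0)  # result is independent of the current state
    return SymbolicSet(u, np.ascontiguousarray(out))


def model_check(phi: H.HCTLFormula, stg: ColouredSTG,
                init: Optional[SymbolicSet] = None) -> SymbolicSet:
    """Satisfaction set of ``phi`` over the coloured STG.

    ``phi`` must have unique quantified names (:func:`bnsketch.hctl.alpha_rename`)
    all of which are declared as auxiliary vectors of the STG's universe.
    ``init`` optionally restricts the colour space further.
    """
    u = stg.universe
    for name in H.quantified_names(phi) | H.free_svars(phi):
        u.aux_axis(name)  # raises on unknown names
    var_index = {v: i for i, v in enumerate(u.variables)}
    core = H.desugar(phi)

    def go(f: H.HCTLFormula) -> SymbolicSet:
        if isinstance(f, H.HConst):
            return u.full_set() if f.value else u.empty_set()
        if isinstance(f, H.HProp):
            if f.name not in var_index:
                raise KeyError(f"unknown proposition {f.name!r}")
            return u.state_var(var_index[f.name])
        if isinstance(f, H.HSVar):
            return u.sv_eq_state(f.name)
        if isinstance(f, H.HNot):
            return ~go(f.arg)
        if isinstance(f, H.HAnd):
            return go(f.left) & go(f.right)
        if isinstance(f, H.HEX):
            return stg.pre_image(go(f.arg))
        if isinstance(f, H.HEU):
            hold, target = go(f.left), go(f.right)
            z = target
            while True:
                znew = target | (hold & stg.pre_image(z))
                if znew.same_as(z):
                    return z
                z = znew
        if isinstance(f, H.HAU):
            hold, target = go(f.left), go(f.right)
            z = target
            while True:
                # all successors already in z (the relation is total)
                all_succ = ~stg.pre_image(~z)
                znew = target | (hold & all_succ)
                if znew.same_as(z):
                    return z
                z = znew
        if isinstance(f, H.HBind):
            return (go(f.arg) & u.sv_eq_state(f.var)).exists_aux(f.var)
        if isinstance(f, H.HAt):
            return _jump(go(f.arg), f.var)
        if isinstance(f, H.HExists):
            return go(f.arg).exists_aux(f.var)
        raise TypeError(f"unexpected node after desugaring: {f!r}")

    result = go(core) & stg.colours
    if init is not None:
        result = result & init
    return result


def colours_satisfying(result: SymbolicSet,
                       mode: SatisfactionMode = "all_states") -> SymbolicSet:
    """Collapse a closed check result onto the colour axis.

    ``all_states``: colours whose every state satisfies the formula;
    ``some_state``: colours with at least one satisfying state.
    """
    leftover = result.depends_on_aux()
    if leftover:
        raise ValueError(
            f"result still depends on state variables {leftover}; "
            "the checked formula was not closed")
    u = result.universe
    arr = result.array
    if mode == "all_states":
        vec = arr.all(axis=0, keepdims=True)
    elif mode == "some_state":
        vec = arr.any(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown satisfaction mode {mode!r}")
    return SymbolicSet(u, vec)


def check_sketch_formula(phi: H.HCTLFormula, stg: ColouredSTG,
                         mode: SatisfactionMode = "all_states") -> SymbolicSet:
    """Colours of the STG whose network satisfies the closed formula ``phi``."""
    if not H.check_closed(phi):
        raise ValueError("dynamic properties must be closed formulae")
    sat = model_check(phi, stg)
    return colours_satisfying(sat, mode) & stg.colours
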
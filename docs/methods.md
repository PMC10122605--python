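# Methods

## Model and semantics

A Boolean network `F = (F_1, .., F_n)` with `F_i : B^n -> B` is given
asynchronous semantics: the state-transition graph (STG) over `B^n` has an
edge `s -> s[i := F_i(s)]` for every `i` with `F_i(s) != s_i`, plus a
self-loop at every fixed point, so the transition relation is total.
An attractor is a bottom strongly connected component of the STG;
attractors are classified as fixed-point (singleton), cyclic (a single
cycle) or complex.

A *partially specified* network (PSBN) allows uninterpreted function
symbols in the update expressions.  An interpretation assigns each symbol
a concrete truth table; specializing the PSBN under an interpretation
yields a concrete network.  A *sketch* combines an influence graph (which
regulations are admissible), a PSBN, a set of first-order update-function
properties, and a set of closed HCTL formulae; the inference problem is to
compute every network consistent with all four components.

Conventions used throughout: states, truth-table rows and colours are read
as unsigned binary numbers with the first variable (or first argument, or
first parameter constant) most significant.

## The inference pipeline

1. **Influence-graph check** (syntactic): every expression may mention
   only the admitted regulators of its variable; otherwise the sketch is
   rejected outright.
2. **Symbol elimination**: each application `f(e_1..e_a)` with `a > 0` is
   replaced by the row-selection expansion
   `OR_b ( c_{f,b} & AND_i (e_i <=> b_i) )` over `2^a` fresh zero-arity
   constants `c_{f,b}` that encode f's truth table.  Zero-arity symbols
   are their own constants.  A valuation of all constants — a *colour* —
   is in bijection with an interpretation of the original symbols, which
   keeps decoding trivial.  The default arity cap is 8 (`2^8` constants
   per symbol); the expansion is doubly exponential in principle, but
   biological in-degrees are small.
3. **Update-function properties**: each property is compiled into the set
   of colours for which it holds of the (eliminated) expression.  Atoms:
   essential(i) = `Ex. f(x[i:=0]) xor f(x[i:=1])`; positive(i) / negative(i)
   = non-strict monotonicity `Ax. f(x[i:=0]) => f(x[i:=1])` (resp. the
   converse); canalizing(i, a, b) = `x_i = a` forces output `b`;
   veto(i, s) = canalizing(i, s, 0).  Atom indices refer to network
   variables, matching how such constraints are stated.  Monotonicity is
   deliberately non-strict (it does not imply essentiality), so signed
   influence-graph edges generate `positive & essential` only when marked
   essential.  Properties combine by intersection; arbitrary Boolean
   combinations are supported *within* one item.
4. **Coloured STG**: the update expressions are compiled into predicates
   `U_i(s, c)`; the transition `s -> s[i := !s_i]` exists at colour `c`
   iff `U_i(s, c) != s_i`, the self-loop predicate is
   `AND_i (U_i(s,c) = s_i)`.  The relation is kept per-variable
   (disjunctively), which is the standard shape for asynchronous
   semantics.
5. **Coloured HCTL model checking**: bottom-up over the formula, on sets
   of (state, state-variable valuation, colour) triples.  `EX` is the
   coloured pre-image; `E[p U q]` and `A[p U q]` are least fixpoints
   (`A[p U q]` is computed directly via the universal pre-image
   `~pre(~Z)`, sound because the relation is total, rather than through
   the `EG` duality).  The binder `!{x}:` conjoins the diagonal
   "valuation of x = current state" and projects x away; the jump `@{x}:`
   replaces the state axis by x's valuation; `3{x}:` projects
   existentially.  Quantified names are made unique at parse time
   (alpha-renaming), so one auxiliary state-vector per name suffices and
   capture is impossible.
6. **Colour collapse**: a colour is consistent with a closed formula when
   the formula holds in **all** states of its STG (default), or in at
   least one (`some_state`, exposed as an option).  All formulae this
   package generates from data are existentially anchored
   (`3{x}: @{x}: ...`), hence state-independent, and the two conventions
   coincide on them; the all-states default is required for universal
   properties such as "no attractor other than these exists".

Two counts are reported at every stage: surviving interpretations
(colours) and semantically distinct networks (different colours may
specialize to identical update tables; deduplication compares the packed
update tables of all surviving colours).  The influence-graph stage uses
the closed form `prod_i 2^(2^(k_i))` with `k_i` the admitted in-degree,
exact in arbitrary precision.

## Symbolic representation

Sets are represented as dense Boolean characteristic arrays with one axis
for the `2^n` states, one per quantified state variable, and one for the
`2^m` colours; an axis of size one means the set does not constrain that
dimension, and numpy broadcasting implements the set algebra without
materializing the full product.  This representation is exact and, for
the problem sizes this package targets (networks up to ~10 variables,
up to ~20 parameter constants), faster in practice than pointer-chasing
decision diagrams in pure Python; it deliberately trades the asymptotic
compression of decision diagrams for vectorized throughput.  Scaling to
hundreds of variables is out of scope.  Hybrid operators only materialize
the axes their subformula actually constrains — binders collapse their
axis immediately — so the peak intermediate size is governed by the
deepest *simultaneously free* state variables, not by the total number of
quantifiers.

## Encoding observations

A steady-state row asserts that some attractor (default) or some fixed
point contains a state matching the observed values:
`3{x}: @{x}: (literals & (!{y}: AG EF {y}))`.  Attractor mode is the
default because unmeasured variables may keep oscillating: an apparent
steady state can sit inside a cyclic or complex attractor.  Unobserved
variables contribute no literal, so partial measurements are supported; a
row with no measured variable is an error.  A time series becomes a
nested reachability chain `3{x}: @{x}: (d_1 & EF (d_2 & EF (...)))`, with
an optional attractor anchor on the last measurement; plain `EF` is used
between measurements (monotone reachability is not modelled).  A
prohibition formula `V{x}: @{x}: ((!{y}: AG EF {y}) => (p_1 | ... | p_k))`
confines all attractors to the given patterns.

## The running example

The bundled three-variable sketch uses influences `v3 -> v1`, `v1 -> v2`,
`{v1, v2, v3} -> v3` and update logic `E1 = f(v3)`, `E2 = g(v1)`,
`E3 = v3 | h(v1, v2)`.  The properties "v3 essential and negative in E1"
force `f` to be the negation, and "v1, v2 essential in E3, v1 positive"
leave `h` one of `v1|v2`, `v1&v2`, `v1|!v2`, `v1&!v2`.  The cascade of
candidate counts — 4096 consistent with the graph, 256 with the PSBN, 16
after the properties, 4 after requiring a shared weak basin of two
attractors (the other 12 candidates are mono-stable), 1 after the two
steady-state observations — and the final decoded candidate
(`g = v1`, `h = v1 & !v2`, a bistable switch whose two fixed points are
exactly the observed states) are all recomputed, not stored: the test
suite derives them both symbolically and with the explicit oracle.  This
exact structure was chosen because it is the unique minimal expression
assignment for which all of those stage counts and the decoded candidate
hold simultaneously.

## Synthetic ground-truth sketches

`random_sketch` samples, per variable, 1..`max_in_degree` regulators
(default 2) and a uniform random update table over them; the influence
graph records exactly those regulations.  A fraction of the update
functions (default 0.5) is replaced by fresh symbols over the same
regulators, subject to a budget of parameter constants (default 12,
keeping the colour space at most 4096); for every regulator in which a
hidden true function is both essential and monotone, the corresponding
sign property is emitted.  Observations (default 2) are drawn uniformly
from the true attractor states and encoded in attractor mode, so the true
network satisfies every generated component by construction — the
recovery tests therefore check soundness of the pipeline, not
identifiability.  What the generator does **not** emulate: measurement
noise or binarization error (observations are exact states of the true
network), partial observability, scale-free topology, or biologically
biased (canalizing-enriched) update functions.  Passing recovery tests
consequently say nothing about robustness to noisy or misbinarized data.

## Numerical and design notes

* Fixpoint iterations are monotone and compared by array equality;
  termination is bounded by the state count per colour slice.
* Enumeration and witness order is the lexicographically smallest colour
  valuation first (first constant most significant), for reproducibility.
* The explicit-state oracle shares no checking logic with the symbolic
  path: it builds the STG as a networkx digraph, takes bottom SCCs from
  the condensation, evaluates HCTL by structural recursion with explicit
  environments, and infers by enumerating interpretations.
* The transition definition treats "update changes the variable" as
  `s != t` with a separate self-loop clause at fixed points; this is the
  only reading under which the relation is total and attractor formulae
  behave.
* Canalizing/veto atoms follow the definitions stated above; `veto` is
  the sign-parameterized forcing of output 0 and is documented at its
  definition site so it can be adjusted if a different convention is
  needed.

## Limitations

* Only asynchronous semantics (synchronous or most-permissive updating
  would need a different transition builder).
* The dense backend caps the colour space at 24 parameter constants and
  the distinct-network deduplication at 20; beyond that only colour
  counts are available.
* No counterexample/witness paths for failed dynamic properties.
* Update-function properties combine by intersection across items.
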
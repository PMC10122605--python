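# bnsketch

Inference of asynchronous Boolean networks from partial knowledge and
binarized data, via coloured model checking of hybrid CTL.

## The problem

A Boolean network (BN) over variables `v1..vn` assigns each variable an
update function `F_i : B^n -> B`; under asynchronous semantics one variable
updates per step, and the long-term behaviours are the *attractors* (bottom
strongly connected components) of the resulting state-transition graph.
When modelling a gene-regulatory or signalling system, the update logic is
rarely known exactly.  What a modeller typically has is

* an **influence graph** `I` — which species may regulate which;
* **partially specified update expressions** `E_i` that may contain
  *uninterpreted function symbols* `f(a)` (fixed but unknown Boolean
  functions), e.g. `E3 = v3 | h(v1, v2)`;
* **update-function properties** `Pi` — first-order constraints such as
  "`v3` is essential and acts negatively in `E1`", canalization, or veto;
* **dynamic properties** `Omega` — closed formulae of hybrid CTL (HCTL)
  over the state-transition graph, including formulae generated
  automatically from binarized steady-state or time-series measurements
  ("some attractor contains a state matching this observation").

The tuple `S = (I, E, Pi, Omega)` is a *network sketch*; the inference
problem is to compute **all** BNs consistent with every component.
`bnsketch` solves it exactly: each symbol of arity `a` is expanded into
`2^a` Boolean parameter constants encoding its truth table, so that a
*colour* (a valuation of all constants) is one candidate network.  The
update-function properties become constraints on colours, and the dynamic
properties are checked for all colours simultaneously on a *coloured*
state-transition graph, by a bottom-up HCTL model checker whose hybrid
operators (`!{x}:` bind, `@{x}:` jump, `3{x}:` exists) make attractors
expressible: `!{x}: AG EF {x}` holds exactly in attractor states, and

```
3{a}: 3{b}: 3{c}: @{c}: (EF {a} & EF {b} & (@{a}: !{x}: AG EF {x})
                         & (@{b}: ((!{y}: AG EF {y}) & ~EF {a})))
```

says two different attractors share a (weak) basin.  The result is the
exact set of consistent candidates, which can be counted, enumerated,
tested for membership, and analysed (e.g. attractor counts for every
candidate at once).

## Worked example

`examples/running_example.json` is a three-variable sketch: influences
`v3 -> v1`, `v1 -> v2`, `v1, v2, v3 -> v3`; update logic `E1 = f(v3)`,
`E2 = g(v1)`, `E3 = v3 | h(v1, v2)`; properties forcing `f` to be the
negation and narrowing `h` to four monotone options; a shared-basin
dynamic property; and two steady-state observations `(0,0,1)` and
`(1,1,0)`.

```
$ bnsketch infer examples/running_example.json
{
  "schema_version": 1,
  "satisfiable": true,
  "stages": [
    {"stage": "IG",                      "interpretations": null, "networks": 4096},
    {"stage": "IG + PSBN",               "interpretations": 256,  "networks": 256},
    {"stage": "IG + PSBN + UFP",         "interpretations": 16,   "networks": 16},
    {"stage": "IG + PSBN + UFP + DP[1]", "interpretations": 4,    "networks": 4},
    {"stage": "IG + PSBN + UFP + DP[2]", "interpretations": 2,    "networks": 2},
    {"stage": "IG + PSBN + UFP + DP[3]", "interpretations": 1,    "networks": 1}
  ],
  "interpretations": 1,
  "distinct_networks": 1
}
```

Reading the cascade: 4096 networks are consistent with the influence graph
alone, 256 with the partially specified logic, 16 interpretations survive
the function properties (four options for `h` times four for `g`), 4 the
shared-basin property (the other 12 candidates have a single attractor),
and the two observations leave exactly one candidate.  Decoding it
(`bnsketch enumerate`) yields `f = negation`, `g = v1`, `h = v1 & !v2`,
i.e. the network `F1 = !v3`, `F2 = v1`, `F3 = v3 | (v1 & !v2)`, whose two
fixed points are precisely the observed states.  Membership of that
network can be confirmed against a `.bnet` file:

```
$ bnsketch check examples/running_example.json examples/final_candidate.bnet
{ "schema_version": 1, "contained": true }
```

The same pipeline is available as a library
(`bnsketch.infer`, `bnsketch.enumerate_candidates`, `bnsketch.contains`,
`bnsketch.attractor_count_per_colour`, ...), together with an explicit
brute-force oracle (`bnsketch.oracle_infer`) used throughout the test
suite as an independent cross-check, and a generator of random
ground-truth sketches (`bnsketch.random_sketch`) for validation.

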
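{
  "variables": [
    "v1",
    "v2",
    "v3"
  ],
  "influences": [
    {
      "source": "v1",
      "target": "v2"
    },
    {
      "source": "v1",
      "target": "v3"
    },
    {
      "source": "v2",
      "target": "v3"
    },
    {
      "source": "v3",
      "target": "v1"
    },
    {
      "source": "v3",
      "target": "v3"
    }
  ],
  "symbols": {
    "f": 1,
    "g": 1,
    "h": 2
  },
  "update_expressions": {
    "v1": "f(v3)",
    "v2": "g(v1)",
    "v3": "v3 | h(v1, v2)"
  },
  "properties": [
    {
      "target": "v1",
      "property": "(essential(v3) & negative(v3))"
    },
    {
      "target": "v3",
      "property": "((essential(v1) & essential(v2)) & positive(v1))"
    }
  ],
  "hctl": [
    "3{a}: 3{b}: 3{c}: @{c}: EF {a} & EF {b} & (@{a}: !{x}: AG EF {x}) & (@{b}: (!{y}: AG EF {y}) & ~EF {a})",
    "3{x}: @{x}: ~v1 & ~v2 & v3 & (!{y}: AG EF {y})",
    "3{x}: @{x}: v1 & v2 & ~v3 & (!{y}: AG EF {y})"
  ]
}
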
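targets, factors
v1, (!v1 & !v2 & !v3) | (!v1 & v2 & !v3) | (v1 & !v2 & !v3) | (v1 & v2 & !v3)
v2, (v1 & !v2 & !v3) | (v1 & !v2 & v3) | (v1 & v2 & !v3) | (v1 & v2 & v3)
v3, (!v1 & !v2 & v3) | (!v1 & v2 & v3) | (v1 & !v2 & !v3) | (v1 & !v2 & v3) | (v1 & v2 & v3)
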
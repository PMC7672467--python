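{
 "base": 1.2,
 "provenance": "Exponential position-weight base of the CCTop off-target penalty; penalty = sum over mismatched positions p of base**p with p 1-based PAM-distal.",
 "schema_version": 1
}
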
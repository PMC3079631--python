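{
  "_comment": "Offsets mapping full-length reference numbering to loop-fragment local coordinates: position_local = position_full - offset. Anchored on the named mutated residues in each loop (H53 in loop A, T85 in loop B, H154 in loop C, Y182 in loop D, A217 in loop E); inferred, not printed coordinates.",
  "loop_A": 45,
  "loop_B": 77,
  "loop_C": 146,
  "loop_D": 177,
  "loop_E": 212
}
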
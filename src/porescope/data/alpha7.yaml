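# Default ring map for the human alpha7 nicotinic receptor pentamer.
# Author numbering anchored at the 13' constriction (Val246); the M2 helix
# spans prime positions -2'..20' (23 residues).  Everything here can be
# overridden by a user-supplied topology file.
chain_ids: [A, B, C, D, E]
prime_map:
  -2: 231
  -1: 232
  0: 233
  1: 234
  2: 235
  3: 236
  4: 237
  5: 238
  6: 239
  7: 240
  8: 241
  9: 242
  10: 243
  11: 244
  12: 245
  13: 246
  14: 247
  15: 248
  16: 249
  17: 250
  18: 251
  19: 252
  20: 253
m2_range: [231, 253]
loops:
  C-loop: [179, 188]
  Cys-loop: [122, 136]
  beta1-beta2: [38, 42]
  M2-M3: [254, 259]
  backwall: [139, 140]
ligand_resname: EPI
key_residues:
  Pro256: 256
  Lys40: 40
  Val13p: 246
  Leu9p: 242
  Leu16p: 249
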
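# Selection file for `memdeform geometry`.
# Chain ids and residue ranges must match the structure file; the ones
# below fit the two-helix synthetic bundle written by `memdeform simulate`.
helices:
  H1: {chain: A, range: [1, 27]}
  H2: {chain: B, range: [1, 27]}

interhelix_angles:
  - [H1, H2]

# For a dimeric structure, name the C2 chain pair to define the membrane
# normal; helix tilts are then reported against it.
# c2_pair: {chain_a: C, chain_b: D}

# Buried-interface pairs (heavy atoms of the listed residue ranges).
# interfaces:
#   - {name: a3p-TMD2, chain_a: A, ranges_a: [[140, 165]],
#      chain_b: B, ranges_b: [[95, 125]]}
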
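# Reference histone definition: HMfB (Histone B, Methanothermus fervidus).
# All positions are 1-based in HMfB numbering; every score and report in the
# package is expressed in this coordinate system.
name: HMfB
sequence: MELPIAPIGRIIKDAGAERVSDDARITLAKILEEMGRDIASEAIKLARHAGRKTIKAEDIELAVRRFKK
length: 69
helix_bounds:
  alpha1: [3, 20]
  alpha2: [26, 55]
  alpha3: [58, 66]
dna_anchor_positions: [10, 19]
hydrophobic_core_positions: [24, 28, 32, 39, 43]
fold_salt_bridge: [52, 59]
dimer_interface_positions: [46, 49, 59, 62]
stacking_interface_positions: [15, 16, 17]
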
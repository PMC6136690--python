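# Idealized hypernucleosome geometry defaults.
# bp_per_dimer: DNA wrapped per histone dimer (~30 bp; one superhelical turn
#   per ~3 dimers, nucleosome-like wrapping density).
# rise_per_dimer: axial advance of the superhelical rod per dimer, nm
#   (nucleosome-like superhelical pitch of ~3 nm per turn / ~3 dimers per turn).
# bp_rise: B-DNA contour length per base pair, nm.
# superhelix_radius: radius of the dimer pseudo-atom helix, nm (coordinate
#   output only; never enters the compaction closed form).
# dimers_per_turn: angular density of the left-handed superhelix (coordinate
#   output only).
bp_per_dimer: 30.0
rise_per_dimer: 1.02
bp_rise: 0.34
superhelix_radius: 3.25
dimers_per_turn: 3.0
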
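# Candidate inter-dimer contact position pairs (HMfB numbering), i.e. positions
# that face a neighbouring dimer layer (offset i+2 or i+3) in the stacked rod.
# layer_offset is "unknown" for all bundled entries; backbone_allowed marks
# pairs where a backbone-carbonyl acceptor can substitute for a polar side chain.
# uncertain marks pairs supported by a single observation.
pos_a	pos_b	layer_offset	backbone_allowed	uncertain
2	48	unknown	false	false
13	18	unknown	false	false
14	18	unknown	false	false
14	41	unknown	true	false
14	44	unknown	true	false
14	48	unknown	true	false
14	53	unknown	false	true
15	41	unknown	true	false
26	57	unknown	false	false
26	58	unknown	false	false
27	57	unknown	false	false
27	58	unknown	false	false
27	61	unknown	false	false
30	61	unknown	false	false
33	48	unknown	false	false
34	45	unknown	false	false
34	61	unknown	false	false
34	65	unknown	false	false
37	41	unknown	false	false
37	45	unknown	false	false
37	48	unknown	false	false
38	41	unknown	false	false
41	41	unknown	false	false
41	45	unknown	false	false
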
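# Curated assessment panel of 33 archaeal histones: per-histone verdicts for
# the dimer-dimer interface and stacking-interface criteria, the enumerated
# potential stacking interactions (HMfB numbering, "(bb)" = backbone-mediated),
# the overall hypernucleosome-formation call, and terminal features.
# Verdicts: plus = likely, pm = uncertain, minus = unlikely.
lineage	histone	dimer	stacking	n_pairs	pairs	overall	features
Heimdall	LC_3 HA	pm	plus	3	E14-R48;K26-E57;R41-E45	pm	N-terminal tail
Heimdall	LC_3 HB	plus	plus	5	E30-K61;Q14-R48;R13-Q18;K27-E57;K37-E45	plus	.
Heimdall	LC_3 HC	pm	plus	3	N34-R65;T15-K41;Y14-Q53	pm	.
Loki	GC14_75 (HLkE)	minus	plus	2	D14-R48;K34-E45	minus	Truncated C-term
Loki	CR_4	plus	plus	2	Q14-D48;Q41-Q41	plus	.
Odin	LCB_4	plus	minus	3	K30-Q61;K14-E18;E38-R41	pm	.
Thor	SMTZ1-45	plus	plus	5	Q30-D61;E34-K65;K14-E48;E37-R41;E26-K58	plus	.
Woese	CG1_02_33_12	plus	plus	4	R14-T48;R34-E61;E26-K57;E37-R41	plus	.
Pace	CG1_02_31_27	plus	plus	4	S30-K61;E34-K65;K14-T48;E37-K45	plus	.
Huber	CG_4_9_14_3_um_filter_31_125 (HA)	pm	plus	2	E14-K48;E14-K18	pm	.
Huber	CG_4_9_14_3_um_filter_31_125 (HB)	plus	plus	2	N30-R61;K34-E65	plus	N-terminal tail
Diaphero	CG_4_10_14_0_2_um_filter_31_5	pm	pm	4	E33-R48;E37-R41;E37-R48;E27-K61	pm	.
Aenigm	CG1_02_38_14	plus	plus	5	E30-K61;D34-R65;E14-H48;A15-K41;E37-K41	plus	.
Micr	M. acidiphilum ARMAN-2	plus	plus	3	E30-K61;K34-Q65;Y2-K48	plus	.
Nanohalo	Haloredivivus sp. G17	pm	minus	2	E27-R61;Q37-E45	minus	Truncated N-term
Nanohalo	Nanosalina sp. J07AB43 (HA)	plus	plus	5	Q30-K61;D34-R65;K14-E48;K14-E18;Q37-Q45	plus	.
Nanohalo	Nanosalina sp. J07AB43 (HB)	minus	pm	2	Q30-R61;D14-K18	minus	.
Nano	N. equitans Kin4-M	plus	plus	4	E30-R61;Q14-K48;Q14(bb)-R41;K37-E45	plus	.
Kor	ARK-16 (HA)	pm	pm	7	R30-E61;Q14-K48;K15-E41;E26-R58;E27-R57;E33-K48;R38-E41	pm	.
Kor	ARK-16 (HB)	plus	plus	3	Y30-E61;D14-K48;R27-E61	plus	.
Thaum	N. gargensis Ga9.2	plus	plus	4	E34-K65;K14-E18;E27-R61;E37-K41	plus	.
Bathy	B23	pm	pm	4	R14-V44;E34-K61;E37-R41;E26-R58	pm	N-terminal tail
Bathy	B24	plus	plus	3	E34-R65;K14-E18;E27-R61	plus	Truncated N-term
Bathy	SMTZ-80	plus	plus	3	E34-K65;K41-E45;E27-R61	plus	.
Cren	C. maquilingensis IC-167	plus	plus	4	D30-K61;N34-R65;K14-E18;Y37-K48	plus	.
Cren	T. pendens Hrk5	plus	plus	4	E30-K61;S14-R48;R37-E45;R13-E18	plus	.
Cren	V. distributa DSM14429	plus	plus	4	D30-K61;Y34-R65;K14(bb)-R48;K14-E18	plus	.
Eury	M. wolinii (HA)	pm	plus	4	N30-E61;E34-K65;E14-K48;K41-E45	pm	.
Eury	M. wolinii (HB)	plus	plus	5	E30-K61;E34-K65;N14-R48;N14-Q18;Q41-Q41	plus	.
Eury	M. jannaschii DSM2661	plus	minus	4	N30-K61;Q14-R48;K37-Q45;D26-R58	pm	C-terminal tail
Eury	M. methylutens	pm	minus	2	D30-K61;S14-E18	minus	.
Eury	T. kodakarensis KOD1 (HTkB)	plus	plus	4	E30-K61;E34-K65;K14-Q48;K26-E58	plus	.
Eury	M. fervidus DSM2088 (HMfB)	plus	plus	3	K30-E61;E34-R65;D14-R48	plus	.
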
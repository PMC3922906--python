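abbrev	AMT1	AMT2	NRT1/PTR	NRT2
Ac	1	4	48	2
Al	6	1	49	6
At	5	1	51	6
Cp	2	1	41	2
Cs	4	2	49	1
Gm	5	5	96	3
Me	5	4	61	3
Mt	4	3	52	1
Mg	6	2	52	7
Pt	6	5	70	6
Prp	3	4	49	2
Rc	4	3	41	4
Vv	1	1	44	0
Bd	2	6	67	5
Os	2	6	65	3
Si	2	6	74	7
Sb	2	6	67	4
Zm	3	5	51	3
Sm	1	0	31	2
Pp	5	10	18	8
Cr	3	0	0	3
Vc	6	0	1	3
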
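compound	sample	mean	sd	reported_significant
formate	T	32	3	no
formate	N	29	8	no
formate	P	221	4	no
methanol	T	48	0	yes
methanol	N	16	3	yes
methanol	P	160	8	yes
formaldehyde	T	33	6	yes
formaldehyde	N	14	1	yes
formaldehyde	P	77	5	yes
DMSP	T	23	3	yes
DMSP	N	16	1	yes
DMSP	P	163	7	yes
methylamine	T	27	1	yes
methylamine	N	18	0	yes
methylamine	P	145	10	yes
glycine betaine	T	41	1	yes
glycine betaine	N	23	3	yes
glycine betaine	P	132	3	yes
TMAO	T	63	5	yes
TMAO	N	26	2	yes
TMAO	P	148	10	yes
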
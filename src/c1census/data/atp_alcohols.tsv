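compound	sample	mean	sd	reported_significant
ethanol	T	57	8	yes
ethanol	N	14	3	yes
ethanol	P	135	15	yes
1-propanol	T	47	6	yes
1-propanol	N	19	4	yes
1-propanol	P	41	3	yes
2-propanol	T	10	1	no
2-propanol	N	11	2	no
2-propanol	P	26	1	no
1-butanol	T	25	7	no
1-butanol	N	23	9	no
1-butanol	P	35	7	no
2-pentanol	T	13	2	no
2-pentanol	N	11	2	no
2-pentanol	P	25	9	no
iso-amyl alcohol	T	18	5	no
iso-amyl alcohol	N	14	2	no
iso-amyl alcohol	P	40	8	no
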
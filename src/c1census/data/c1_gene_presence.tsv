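pathway	family	HTCC1062	HTCC1002	HTCC7211
THF-linked oxidation	fdhF	+	+	+
THF-linked oxidation	fdsB	+	+	+
THF-linked oxidation	fdhD	+	+	+
THF-linked oxidation	mobA	+	+	+
THF-linked oxidation	moeA	+	+	+
THF-linked oxidation	fhs	+	+	+
THF-linked oxidation	metF	+	+	+
THF-linked oxidation	folD	+	+	+
methanol oxidation	Fe-ADH	+	+	+
methylamine oxidation	glnT	+	+	+
methylamine oxidation	glxBCD	+	+	+
methylamine oxidation	soxBDAG	+	+	+
GBT oxidation	bhmT	+	+	+
GBT oxidation	sardh	+	+	+
GBT oxidation	dmgdh	+	+	+
AMTs	gcvT	+	+	+
AMTs	dmdA	+	+	+
AMTs	putative-AMT	+	+	+
GSH dependent pathway	gfa	-	-	+
GSH dependent pathway	GD-FALDH	-	-	+
GSH dependent pathway	FGH	-	-	+
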
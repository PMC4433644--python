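role	gene	degree	connecting_score
hub	STAT5B	17
hub	EGFR	16
hub	PDGFRB	16
hub	STAT5A	16
intra	RAF1		8
intra	PDGFRB		7
intra	SRC		6
intra	PRKACA		6
intra	EGFR		4
inter	PRKCA		8
inter	MAPK1		7
inter	MAPK3		7
inter	ESR1		6
inter	FYN		6
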
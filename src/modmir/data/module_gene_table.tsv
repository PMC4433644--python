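module_id	gene	is_deg
M01	DPM3	0
M01	DPM1	0
M01	DPM2	1
M02	HIRA	1
M02	HIST2H2BE	1
M02	HIRIP3	1
M03	EGFR	0
M03	PDGFRB	0
M03	PTPN11	0
M03	SHC1	0
M03	SRC	1
M03	STAT5A	1
M03	STAT5B	1
M03	CBL	0
M04	CSNK2A1	0
M04	NCL	0
M04	TOP1	1
M04	TP53	1
M05	NR3C1	0
M05	POU2F1	1
M05	RARA	0
M05	STAT5A	1
M05	STAT5B	1
M05	NCOR2	0
M06	LRP1	1
M06	SKIL	0
M06	SNX17	0
M07	GNB2	0
M07	GNG4	0
M07	RAF1	1
M08	EGFR	0
M08	INSR	0
M08	LEPR	0
M08	PDGFRA	1
M08	PDGFRB	0
M08	SNX6	0
M08	SNX1	1
M08	SNX2	0
M08	SNX4	0
M08	ACVR1B	0
M08	ACVR2B	0
M09	EGFR	0
M09	JAK2	0
M09	PDGFRB	0
M09	PTPN2	0
M09	PTPN11	0
M09	SRC	1
M09	STAT1	0
M09	STAT3	0
M09	STAT5A	1
M09	STAT5B	1
M10	SIRT1	1
M10	HEY2	0
M10	HES1	1
M11	WNT4	0
M11	SFRP1	0
M11	FZD6	1
M12	PABPC1	0
M12	HNRNPD	1
M12	PCBP1	1
M12	PCBP2	1
M13	PRKACA	0
M13	RAF1	1
M13	RAP1A	1
M13	BRAF	0
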
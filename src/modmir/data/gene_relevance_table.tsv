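gene	relevance_score
TP53	10.19
EGFR	10.17
RARA	9.54
SRC	9.48
BRAF	9.37
TOP1	9.37
STAT3	9.32
SFRP1	9.26
RAF1	9.18
STAT1	9.1
LEPR	9.08
STAT5A	8.89
PCBP2	8.43
HNRNPD	8.32
PDGFRB	0.18
PDGFRA	-0.21
NCL	-0.29
PRKACA	-0.39
NR3C1	-0.44
CSNK2A1	-0.52
FZD6	-0.59
INSR	-0.59
PTPN11	-0.64
JAK2	-0.77
WNT4	-0.87
RAP1A	-0.95
SNX1	-1.01
PTPN2	-1.13
PABPC1	-1.16
POU2F1	-1.25
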
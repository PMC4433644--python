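# Tabulated miRNA and target change directions for the eight module
# regulators, one row per (miRNA, target) pair.
# Note: the surrounding narrative describes hsa-miR-491-3p in the opposite
# orientation (miRNA down, RAP1A up); this table records the tabulated
# directions unchanged and the discrepancy is left unresolved.
mirna	mirna_direction	target_gene	target_direction
hsa-miR-499-5p	Up	TOP1	up
hsa-miR-549	Up	TOP1	up
hsa-miR-205	Up	LRP1	down
hsa-miR-525-5p	down	WNT4	down
hsa-miR-21	Up	PCBP1	down
hsa-miR-21	Up	PCBP2	down
hsa-miR-323-3p	down	PCBP1	down
hsa-miR-323-3p	down	PCBP2	down
hsa-miR-423-3p	down	PABPC1	up
hsa-miR-491-3p	Up	RAP1A	down
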
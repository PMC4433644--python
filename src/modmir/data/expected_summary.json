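{
  "unique_module_genes": 54,
  "deg_percent": 38.89,
  "relevance_overlap_count": 30,
  "relevance_overlap_percent": 55.56,
  "anti_correlated_mirnas": 4,
  "hub_genes": ["STAT5B", "EGFR", "PDGFRB", "STAT5A"]
}
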
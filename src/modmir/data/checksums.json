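{
 "gene_relevance_table.tsv": "b0c8fa2d8b32b192594dcb03c0639152d4d798322da64ce43a73c5c395864011",
 "mirna_direction_table.tsv": "68735afca68c9c25e2cbf11d7d27f2f661aa51d31534b19347fbf8bd064a2305",
 "module_gene_table.tsv": "5dfaddc661d09bca5eb64eaedbbe85d9d5ad051f5fb4ade3c95cbce4dad5a52a",
 "topology_table.tsv": "ff42a36c3465e7771d3d1c86fbd0c0ef9fcd4a1d80e67dca44c2a73859b679e7"
}
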
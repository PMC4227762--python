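{
  "n_traced_loci": 19850891,
  "n_filtered_loci": 486090,
  "n_stage1_pass": 1757,
  "n_significant_loci": 80,
  "stage1_alpha": 0.005,
  "fdr_q": 0.1
}
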
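{
  "seed": 1,
  "out_dir": "famrisk_out",
  "simulate": {
    "n_cd": 20,
    "n_uc": 20,
    "n_shared": 15,
    "include_nod2": true,
    "n_controls": 300
  },
  "ibd": {"min_support": 2, "max_conflicts": 0, "max_af": 0.03},
  "filter": {"min_quality": 35.0, "max_af": 0.03, "max_gene_distance": 2}
}
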
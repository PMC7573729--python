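{
  "branch_omega": {
    "fam1_g1": 0.2,
    "fam1_g2": 0.2,
    "fam1_g3": 0.2,
    "fam1_g4": 0.2,
    "fam1_g5": 0.2,
    "fam1_g6": 0.2,
    "fam1_g7": 0.2,
    "fam1_g8": 0.2,
    "n1": 0.2,
    "n2": 0.2,
    "n3": 0.2,
    "n4": 0.2,
    "n5": 0.2,
    "n6": 0.2
  },
  "config": {
    "base_freqs": [
      0.25,
      0.25,
      0.25,
      0.25
    ],
    "birth_rate": 2.0,
    "burst_branches": [],
    "drift_sigma2": 0.01,
    "gene_prefix": "fam1_",
    "jump": 3.0,
    "kappa": 2.0,
    "n_codons": 300,
    "n_tips": 8,
    "n_tissues": 12,
    "omega": 0.2,
    "omega_burst": 1.0,
    "regime": "gradual_bm",
    "seed_expression": 20240103,
    "seed_sequence": 20240102,
    "seed_tree": 20240101,
    "sigma2": 1.0,
    "tip_noise": 2.0
  },
  "expected_mantel_sign": "positive",
  "newick": "((fam1_g1:0.28714485208798607,((fam1_g2:0.047534558667618264,fam1_g3:0.047534558667618264)n3:0.029973699191104777,fam1_g4:0.07750825785872305)n2:0.209636594229263)n1:0.24982577162628491,((fam1_g5:0.007885960788807586,fam1_g6:0.007885960788807586)n5:0.3793267292063596,(fam1_g7:0.2545940273448719,fam1_g8:0.2545940273448719)n6:0.13261866265029526)n4:0.14975793371910376)root;"
}
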
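{
  "branch_omega": {
    "fam3_g1": 0.2,
    "fam3_g2": 0.2,
    "fam3_g3": 0.2,
    "fam3_g4": 0.2,
    "fam3_g5": 0.2,
    "fam3_g6": 0.2,
    "fam3_g7": 0.2,
    "fam3_g8": 0.2,
    "n1": 1.0,
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
    "burst_branches": [
      "n1"
    ],
    "drift_sigma2": 0.01,
    "gene_prefix": "fam3_",
    "jump": 3.0,
    "kappa": 2.0,
    "n_codons": 300,
    "n_tips": 8,
    "n_tissues": 12,
    "omega": 0.2,
    "omega_burst": 1.0,
    "regime": "neo_burst",
    "seed_expression": 20240123,
    "seed_sequence": 20240122,
    "seed_tree": 20240121,
    "sigma2": 1.0,
    "tip_noise": 2.0
  },
  "expected_mantel_sign": "none",
  "newick": "((((fam3_g1:0.11530217804574036,fam3_g2:0.11530217804574036)n3:0.08098364973794786,fam3_g3:0.19628582778368822)n2:0.10974514577470815,fam3_g4:0.30603097355839637)n1:0.42368268119559127,(fam3_g5:0.5400066003151605,(fam3_g6:0.22795084074023614,(fam3_g7:0.02734035240656471,fam3_g8:0.02734035240656471)n6:0.20061048833367143)n5:0.31205575957492426)n4:0.18970705443882724)root;"
}
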
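{
  "alpha": 1.0,
  "boot_n": 25,
  "classes": [
    {
      "codon_fasta": "fam1/codon.fasta",
      "name": "fam1",
      "protein_fasta": "fam1/protein.fasta"
    },
    {
      "codon_fasta": "fam2/codon.fasta",
      "name": "fam2",
      "protein_fasta": "fam2/protein.fasta"
    },
    {
      "codon_fasta": "fam3/codon.fasta",
      "name": "fam3",
      "protein_fasta": "fam3/protein.fasta"
    }
  ],
  "expression_tsv": "expression.tsv",
  "model": "GTR+G+I",
  "p_inv": 0.0,
  "perms": 999,
  "seed": 1
}
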
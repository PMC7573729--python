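# dupdiv

Divergence analysis of duplicated gene families: did paralogues diverge by
**sub-functionalization** (partitioning the ancestral expression domains
among copies) or **neo-functionalization** (accelerated protein change
creating new function)?

The package is aimed at molecular evolution researchers working with
moderate-size gene families (think plant SNAREs: a few classes of a handful
of paralogues each, with an expression atlas over tissues and developmental
stages). It combines:

* **maximum-likelihood genetic distances** under JC69 / GTR+G+I / JTT+G+I,
  neighbor-joining trees with bootstrap supports, and cophenetic distances;
* **expression divergence** as Pearson correlation distance (1 − r) on
  per-gene standardized profiles, with optional centroid-linkage
  clustering;
* **dN/dS (ω)** per gene pair by Nei–Gojobori (1986) counting with the
  validity filter 0 < ω < 9;
* **Mantel permutation tests** within gene classes (expression ~ genetic,
  expression ~ ω), matrix regression (ω ~ genetic), and between-class
  linear models of class means weighted by sample size;
* a **synthetic gene-family generator** (Yule duplication trees, Gillespie
  codon evolution with per-branch ω, and three expression regimes —
  gradual Brownian drift, rapid domain partitioning, ω-burst
  neo-functionalization) that makes the whole pipeline testable end to end.

The inferential logic: under gradual divergence, expression distance
increases with genetic distance, so the within-class Mantel test is
significant. Rapid post-duplication partitioning saturates expression
divergence at the first duplication separating two genes, masking that
relationship. Elevated ω coupled to expression change points to
neo-functionalization.

## Worked example

The repository ships a small synthetic dataset under `fixtures/` — three
gene classes of 8 paralogues each (300 codons, 12 tissues), one per
expression regime: `fam1` gradual drift, `fam2` rapid partitioning, `fam3`
ω-burst. Run the full analysis and summarize it:

```bash
dupdiv run --config fixtures/pipeline_config.json --out report/
dupdiv report --json report/report.json
```

which prints:

```
run e1a14cf65fa3483e (model GTR+G+I, seed 1)
class fam1:
  mantel_expression_genetic: r=0.760 p=0.001 (n=28 pairs)
  mantel_expression_omega: r=-0.460 p=0.968 (n=27 pairs)
  regression_omega_genetic: beta=-0.001 r2=0.000 p=0.543
class fam2:
  mantel_expression_genetic: r=-0.002 p=0.495 (n=28 pairs)
  mantel_expression_omega: r=-0.250 p=0.896 (n=27 pairs)
  regression_omega_genetic: beta=0.010 r2=0.003 p=0.384
class fam3:
  mantel_expression_genetic: r=0.539 p=0.007 (n=28 pairs)
  mantel_expression_omega: r=0.533 p=0.006 (n=28 pairs)
  regression_omega_genetic: beta=0.241 r2=0.901 p=0.002
```

Reading it: the gradual-drift class (`fam1`) shows the positive
expression~genetic association expected under gradual sub-functionalization
(r = 0.76, one-sided permutation p = 0.001 over the 28 gene pairs); the
rapid-partition class (`fam2`) shows none (r ≈ 0, p = 0.5) — its expression
divergence saturated at duplication, masking the relationship; and the
ω-burst class (`fam3`) couples expression change to ω (r = 0.53, p = 0.006)
with a strong ω~genetic regression (r² = 0.90), the neo-functionalization
signature. The report directory also contains, per class, the distance
matrices (TSV), the NJ tree with bootstrap supports (Newick), the ω pair
table with validity reasons, and a checksum manifest; reruns with the same
config are byte-identical.

Other entry points: `dupdiv simulate` (generate a dataset from a
simulation config), `dupdiv distances`, `dupdiv kaks`, `dupdiv expression`,
`dupdiv tree`, `dupdiv divergence` (Mantel test between two distance-matrix
TSVs) — each a thin wrapper over the library functions in `dupdiv.*`.

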
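# Methods

`dupdiv` tests two classic hypotheses about the fate of duplicated genes.
Under **sub-functionalization**, paralogues partition the ancestral gene's
expression domains: different tissues or developmental stages come to
express predominantly one copy. Under **neo-functionalization**, one copy
acquires a new function, typically through accelerated amino-acid change.
The two hypotheses leave different statistical fingerprints in a gene
family: gradual functional drift predicts that expression divergence grows
with genetic divergence, whereas rapid post-duplication partitioning
saturates expression divergence almost immediately and so *masks* any such
relationship; accelerated protein change shows up as elevated dN/dS tied to
expression change.

## Distances

**Expression divergence.** Gene expression profiles (genes x samples) are
scaled per gene to mean 0 and sample (n-1) standard deviation 1; constant
profiles are dropped and reported. The divergence between two genes is the
Pearson correlation distance d = 1 - r over samples, in [0, 2]. Because r
is affine-invariant, the scaling does not change d; it matters only for the
optional centroid-linkage clustering, which operates on the same distances
via the Lance-Williams recursion (centroid heights may show inversions;
they are preserved, not repaired; ties broken by the smallest cluster-index
pair).

**Genetic divergence.** Pairwise maximum-likelihood distances under a
reversible substitution model with discrete-gamma plus invariant-sites rate
variation. The per-pair log-likelihood

  l(t) = sum_sites log[ p_inv 1(x=y) pi_x + (1-p_inv) (1/K) sum_k pi_x P_xy(t r_k) ]

is maximized over t in [0, 10] by bounded Brent search (tolerance 1e-9 on
t). Sites with a gap or ambiguity in either sequence are excluded pairwise.
An optimum at the upper bound marks the pair *saturated*; saturated pairs
are masked, never clamped. Supported models: JC69; GTR with configurable
frequencies/exchangeabilities (defaults: empirical frequencies, all-equal
exchangeabilities — model selection is upstream of this package); and the
JTT amino-acid model with its published exchangeability table and
frequencies embedded. Discrete gamma uses K equal-probability categories
(default K=4, alpha=1, p_inv=0) whose rates are the exact bin means of a
Gamma(alpha, alpha) density, normalized to mean 1.

Trees are built from the ML distance matrix by Saitou-Nei neighbor joining
(deterministic: ties resolved by the lexicographically smallest tip-label
pair; negative branch-length estimates clamped to 0), with supports from
column-resampling bootstrap (default 100 replicates; replicates whose
distance matrix contains saturated pairs are dropped and counted, >50%
dropped is an error). The genetic distance consumed by the inferential
stage defaults to the *cophenetic* (patristic) distances of this tree; raw
pairwise ML distances are available by flag. NJ + cophenetic is the
package's deliberate desk-scale stand-in for a full ML tree search: the
downstream tests consume only a genetic distance matrix, so the estimator
is pluggable.

**Selection.** Per-pair dN/dS by unweighted Nei-Gojobori (1986) counting.
Codons with a gap, ambiguity, or stop in either sequence are excluded.
Synonymous site counts exclude mutations to stop codons from the
denominator; difference counts average synonymous/nonsynonymous steps over
all minimal substitution pathways that avoid stop codons, with equal
weights. Proportions are Jukes-Cantor corrected, D = -(3/4) ln(1-(4/3)p).
A pair is valid when both corrections are defined and 0 < omega < 9;
invalid pairs keep a reason code (identical, zero-synonymous, saturation,
omega out of range) and are masked. NG86's equal-rate correction assumes no
transition/transversion bias; on data generated with kappa = 2 it
underestimates omega by roughly 10%, which is why the estimator-recovery
checks run at kappa = 1.

## Inference

**Within classes.** Mantel permutation tests between distance matrices:
the statistic is the Pearson correlation over unmasked off-diagonal pairs;
the null is built by jointly permuting the row/column labels of the second
matrix, with its mask travelling along (pairwise exclusion, so a missing
omega masks a pair, never a gene). Tests are one-sided (upper) by default
because the hypotheses concern positive association; two-sided by flag.
With 7 or fewer labels all n! permutations are enumerated and the p-value
is exact; otherwise 999 seeded Monte-Carlo permutations with the
(1+b)/(1+m) convention, so p is never exactly 0. Matrix regression (OLS of
one vectorized matrix on another, permutation p for the slope) quantifies
omega ~ genetic-distance relationships.

**Between classes.** Per class and distance kind, the mean, sample SD and
number of usable pairs are computed; class means are then related by least
squares weighted by the class pair count, with the slope's p-value from a
t statistic on n-2 degrees of freedom (at least 3 classes required).
Equal weights reduce exactly to OLS. No multiple-testing correction is
applied across classes; p-values are reported raw.

## The synthetic generator

The generator produces gene families with the statistical structure the
analysis assumes, so every stage can be validated without external data.

* **Tree**: Yule pure-birth duplication tree; waiting times exponential
  with rate (lineages x birth rate), plus a final exponential stretch so
  terminal branches are positive. Expected root-to-tip depth is
  sum_{k=2..n} 1/(lambda k).
* **Codon sequences**: Gillespie single-nucleotide simulation along each
  branch. Proposals follow an HKY-style rate matrix (kappa, base
  frequencies) normalized to one expected proposal per site per unit branch
  length; proposals creating stops are rejected; nonsynonymous proposals
  are accepted with the branch's omega (so omega is exactly the realized
  acceptance ratio and must lie in [0, 1] — neo-functionalization bursts
  use omega up to 1 *plus* expression jumps rather than omega > 1); no
  indels, so the true alignment is the identity.
* **Expression**, evolved on the log scale and exponentiated for output:
  - `gradual_bm` — per-tissue Brownian drift with rate sigma2 (default 1)
    along every branch; expression distance grows with patristic distance.
  - `rapid_partition` — nested complementary domain partitioning: each
    duplication splits the parent's retained-tissue set into two random
    complementary halves, one per daughter, so every pair of extant genes
    ends up with disjoint expression domains; a tip expresses `jump`
    (default 3) in its retained tissues. Divergence therefore saturates at
    the first duplication separating two genes, independent of branch
    lengths — the mechanism by which rapid sub-functionalization masks the
    distance-divergence relationship. Tissue-level noise (`tip_noise`,
    default 2) represents biological/measurement variability; its default
    was set by simulation so that the partition structure, not residual
    tree-depth signal carried by domain sizes, dominates pairwise
    divergence (at the default, mean Mantel r is 0.03 and the one-sided
    rejection rate is within one point of the nominal 5% over 400
    fixture-scale replicates).
  - `neo_burst` — small drift everywhere plus partition-style jumps
    confined to designated burst branches, which can also carry elevated
    omega.

Defaults define the reference study conditions used throughout the tests:
8 genes per family, birth rate 2 (so root-to-tip depth ~0.86 expected
substitutions/site), 300 codons, kappa 2, uniform base frequencies,
background omega 0.2, 12 tissues. At this scale the gradual-drift regime
yields a significant within-class expression~genetic Mantel test in ~92% of
runs and the rapid-partition regime in ~5% — the package's operational
version of the sub-functionalization masking argument. A packaged 3-class
fixture (one class per regime) ships under `fixtures/` and regenerates
bit-identically from the seeds recorded in its truth files.

What the generator does **not** emulate: indels and alignment error, gene
loss/pseudogenization, among-site omega variation, expression count noise
models (profiles are log-normal, not negative-binomial), and correlated
tissues. Passing the simulation-based checks therefore demonstrates the
statistical machinery is correct under the stated model, not that real
expression atlases satisfy these assumptions.

## Numerical conventions

Transition matrices come from the symmetrized spectral decomposition of Q
(exact for reversible models), clipped at 0 and row-renormalized to absorb
rounding. All TSV output uses tab separation, UTF-8 and `%.17g` floats, so
reruns are byte-identical; every stochastic stage takes an explicit seed
and the run log records all of them. Degenerate inputs fail loudly:
constant expression rows, saturated distance pairs, zero usable codons,
masked matrices reaching complete-matrix algorithms, and sub-minimal pair
counts each raise a specific error rather than propagating NaNs.

## Known limitations

* NJ on a non-additive (noisy) matrix is a heuristic; bootstrap supports
  quantify but do not remove that uncertainty.
* NG86 underestimates omega under transition bias and cannot use omega > 1
  generating processes in the simulator (acceptance-probability design).
* The between-class weighted regression treats class means as independent
  points; phylogenetic non-independence between classes is not modeled.
* Pathway-averaged NG86 difference counts can attribute fractional
  nonsynonymous differences to purely synonymous histories when two
  synonymous hits land in one codon (e.g. Leu TTA/CTC); with omega = 0 the
  exact invariant is identity of the translated proteins, which is what the
  tests assert.
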
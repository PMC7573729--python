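"""Maximum-likelihood pairwise distances, neighbor joining, and bootstrap support.

The pairwise distance between two aligned sequences under a reversible model
with a gamma + invariant-sites rate mixture maximizes

    l(t) = sum_sites log[ p_inv 1(x=y) pi_x
                          + (1 - p_inv) (1/K) sum_k pi_x P_xy(t r_k) ]

over t in [0, t_max].  Sites where either sequence has a gap or ambiguity are
excluded pairwise.  An optimum at t_max is flagged as saturated; saturated
pairs are masked in distance matrices rather than clamped.

Trees are estimated from the distance matrix by Saitou-Nei neighbor joining
(exact on additive matrices), with ties broken by the lexicographically
smallest tip-label pair and negative branch-length estimates clamped to zero.
Bootstrap supports come from resampling alignment columns with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .distmatrix import DistanceMatrix
from .errors import DupdivError, IncompleteMatrixError, InsufficientDataError
from .models import RateMixture, SubstitutionModel

T_MAX = 10.0
_XATOL = 1e-9


@dataclass(frozen=True)
class PairwiseDistance:
    distance: float
    saturated: bool
    n_sites: int


def _encode(seq: str, model: SubstitutionModel) -> np.ndarray:
    idx = model.state_index()
    return np.array([idx.get(c, -1) for c in seq], dtype=np.int64)


def _pair_counts(a: str, b: str, model: SubstitutionModel) -> np.ndarray:
    if len(a) != len(b):
        raise DupdivError("sequences must be aligned to equal length")
    x = _encode(a, model)
    y = _encode(b, model)
    use = (x >= 0) & (y >= 0)
    s = len(model.states)
    counts = np.bincount(x[use] * s + y[use], minlength=s * s).reshape(s, s)
    return counts.astype(float)


def _neg_log_lik(counts, model, mixture):
    pi = model.pi
    eye = np.eye(len(pi))
    k = len(mixture.rates)
    p_inv = mixture.p_inv

    def nll(t):
        f = np.zeros_like(counts)
        for r in mixture.rates:
            f += model.transition_matrix(t * r)
        f = pi[:, None] * f / k
        f = p_inv * eye * pi[:, None] + (1.0 - p_inv) * f
        with np.errstate(divide="ignore"):
            logf = np.where(counts > 0, np.log(np.maximum(f, 1e-300)), 0.0)
        return -float((counts * logf).sum())

    return nll


def ml_pairwise_distance(
    a: str,
    b: str,
    model: SubstitutionModel,
    mixture: RateMixture = RateMixture(),
    t_max: float = T_MAX,
) -> PairwiseDistance:
    """ML distance between two aligned sequences; see module docstring."""
    counts = _pair_counts(a, b, model)
    n_sites = int(counts.sum())
    if n_sites == 0:
        raise InsufficientDataError("no usable sites shared by the pair")
    off_diag = counts.sum() - np.trace(counts)
    if off_diag == 0:
        return PairwiseDistance(0.0, False, n_sites)
    nll = _neg_log_lik(counts, model, mixture)
    res = minimize_scalar(
        nll, bounds=(0.0, t_max), method="bounded", options={"xatol": _XATOL}
    )
    t_hat = float(res.x)
    saturated = t_hat >= t_max * (1.0 - 1e-5)
    return PairwiseDistance(t_hat, saturated, n_sites)


def distance_matrix(
    aln: Alignment,
    model: SubstitutionModel,
    mixture: RateMixture = RateMixture(),
    t_max: float = T_MAX,
) -> DistanceMatrix:
    """All pairwise ML distances; saturated pairs are masked."""
    if aln.n_seqs < 2:
        raise InsufficientDataError("distance matrix requires >= 2 sequences")
    n = aln.n_seqs
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            pd = ml_pairwise_distance(aln.rows[i], aln.rows[j], model, mixture, t_max)
            if pd.saturated:
                mask[i, j] = mask[j, i] = True
            else:
                values[i, j] = values[j, i] = pd.distance
    return DistanceMatrix(aln.ids, values, mask)


# ----------------------------------------------------------------------
# Neighbor joining
# ----------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic lexicographic ties.

    Negative branch-length estimates are clamped to 0.  The returned tree is
    unrooted, stored with a trifurcating root.
    """
    if not dm.is_complete:
        raise IncompleteMatrixError("neighbor joining requires a complete matrix")
    if dm.n < 3:
        raise InsufficientDataError("neighbor joining requires >= 3 taxa")

    taxon_ns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    rep: dict[int, str] = {}  # lexicographic representative (min tip label)
    for i, label in enumerate(dm.labels):
        taxon = taxon_ns.new_taxon(label)
        nodes[i] = dendropy.Node(taxon=taxon)
        rep[i] = label

    d = {}
    active = list(range(dm.n))
    for i in active:
        for j in active:
            if i < j:
                d[(i, j)] = float(dm.values[i, j])

    def dist(i, j):
        return d[(min(i, j), max(i, j))]

    next_id = dm.n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                tie = tuple(sorted((rep[i], rep[j])))
                cand = (q, tie)
                if best is None or cand < best:
                    best = cand
                    best_pair = (i, j)
        i, j = best_pair
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        rep[next_id] = min(rep[i], rep[j])
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, next_id), max(k, next_id))] = max(
                0.5 * (dist(i, k) + dist(j, k) - dij), 0.0
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # final trifurcation: three-point formulas
    a, b, c = sorted(active, key=lambda k: rep[k])
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root = dendropy.Node()
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[node_id])
        nodes[node_id].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ----------------------------------------------------------------------
# Bootstrap
# ----------------------------------------------------------------------

def _splits(tree: dendropy.Tree, all_labels: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side excluding the
    lexicographically smallest label."""
    ref = min(all_labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel,
    mixture: RateMixture = RateMixture(),
    n_boot: int = 100,
    seed: int = 0,
    t_max: float = T_MAX,
) -> dendropy.Tree:
    """NJ tree from the full alignment, with column-resampling bootstrap
    supports attached to internal nodes (as both ``.support`` and the Newick
    internal-node label).

    Replicates whose distance matrix has saturated (masked) pairs are dropped
    and counted; more than 50% dropped is an error.
    """
    if n_boot < 1:
        raise DupdivError("n_boot must be >= 1")
    point = nj_tree(distance_matrix(aln, model, mixture, t_max))
    all_labels = frozenset(dm_label for dm_label in aln.ids)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    kept = 0
    dropped = 0
    for _ in range(n_boot):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rep = aln.select_columns(cols)
        try:
            dm = distance_matrix(rep, model, mixture, t_max)
            if not dm.is_complete:
                dropped += 1
                continue
            rep_tree = nj_tree(dm)
        except DupdivError:
            dropped += 1
            continue
        kept += 1
        for split in _splits(rep_tree, all_labels):
            counts[split] = counts.get(split, 0) + 1
    if dropped > n_boot // 2:
        raise DupdivError(
            f"bootstrap failure: {dropped}/{n_boot} replicates dropped"
        )
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if min(all_labels) in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            support = counts.get(side, 0) / kept
            node.support = support
            node.label = f"{support:.6g}"
    point.bootstrap_replicates_kept = kept
    point.bootstrap_replicates_dropped = dropped
    return point
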
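"""Expression scaling, Pearson correlation distances, and centroid clustering.

Expression matrices are gene x sample pandas DataFrames.  Each gene's profile
is scaled to mean 0 and sample (n-1) standard deviation 1; constant profiles
carry no correlation information and are dropped with a warning record.  The
pairwise expression distance is 1 - Pearson r (range [0, 2]).  Gene clustering
uses centroid linkage computed by the Lance-Williams recursion; centroid
heights can show inversions, which are preserved as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distmatrix import DistanceMatrix
from .errors import DupdivError, IdError, IncompleteMatrixError, ParseError


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a gene x sample TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise IdError(f"duplicate gene id(s): {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise IdError(f"duplicate sample id(s): {dups}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"non-numeric or non-finite cell at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return numeric.astype(float)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class ScalingReport:
    dropped_constant: list[str] = field(default_factory=list)


def scale_rows(expr: pd.DataFrame, report: ScalingReport | None = None) -> pd.DataFrame:
    """Scale each gene to mean 0, sample sd 1; drop constant genes.

    Requires at least 2 samples.  Returns the scaled matrix; ids of dropped
    constant genes are appended to ``report`` when given.
    """
    if expr.shape[1] < 2:
        raise DupdivError("scaling requires at least 2 samples per gene")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if report is not None:
        report.dropped_constant.extend(expr.index[~keep].tolist())
    kept = values[keep]
    scaled = (kept - kept.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(scaled, index=expr.index[keep], columns=expr.columns)


def correlation_distance(expr: pd.DataFrame) -> DistanceMatrix:
    """Pairwise 1 - Pearson r over samples, for every gene pair."""
    if expr.shape[1] < 3:
        raise DupdivError("correlation distance requires at least 3 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        gene = expr.index[np.flatnonzero(sd == 0)[0]]
        raise DupdivError(f"correlation undefined for constant gene {gene!r}")
    r = np.corrcoef(values)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(expr.index, d)


@dataclass(frozen=True)
class Dendrogram:
    """Sequence of agglomerative merges over the leaf labels.

    ``merges`` rows are (cluster_a, cluster_b, height, new_size); original
    leaves are clusters 0..n-1 and merge k creates cluster n+k, as in the
    standard linkage-matrix convention.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self):
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")

    def linkage_matrix(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )


def cluster_centroid(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative centroid-linkage clustering of a complete distance matrix.

    Uses the Lance-Williams update for centroid linkage on squared distances:
    d2(k, i+j) = (ni*d2(k,i) + nj*d2(k,j))/(ni+nj) - ni*nj*d2(i,j)/(ni+nj)^2.
    Merge heights are the (unsquared) centroid distances; inversions are kept.
    Ties are broken by the smallest (a, b) cluster-index pair.
    """
    if not dm.is_complete:
        raise IncompleteMatrixError("clustering requires a complete distance matrix")
    n = dm.n
    d2 = {}  # squared inter-cluster distances, keyed by frozenset of cluster ids
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dm.values[i, j] ** 2
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                key = (min(a, b), max(a, b))
                cand = (d2[key], key[0], key[1])
                if best is None or cand < best:
                    best = cand
        h2, a, b = best
        na, nb = size[a], size[b]
        merges.append((a, b, float(np.sqrt(max(h2, 0.0))), na + nb))
        active = [c for c in active if c not in (a, b)]
        for c in active:
            dca = d2[(min(a, c), max(a, c))]
            dcb = d2[(min(b, c), max(b, c))]
            d2[(c, next_id)] = (
                (na * dca + nb * dcb) / (na + nb) - na * nb * h2 / (na + nb) ** 2
            )
        size[next_id] = na + nb
        active.append(next_id)
        next_id += 1
    return Dendrogram(dm.labels, tuple(merges))


def dendrogram_newick(dend: Dendrogram) -> str:
    """Serialize a dendrogram as Newick with node heights encoded as lengths.

    Branch length of a child = parent merge height - child merge height
    (leaves have height 0).  Inverted merges can yield negative lengths;
    they are written as-is, since the heights are the data.
    """
    n = len(dend.labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: dend.labels[i] for i in range(n)}
    for k, (a, b, h, _s) in enumerate(dend.merges):
        nid = n + k
        la = h - height[a]
        lb = h - height[b]
        node[nid] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
        height[nid] = h
    return node[n + len(dend.merges) - 1] + ";"
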
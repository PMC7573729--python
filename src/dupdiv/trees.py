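"""Tree input/output and cophenetic (patristic) distances.

Trees are held as :class:`dendropy.Tree` objects.  Bootstrap supports are
serialized as internal node labels in Newick, the most interoperable dialect.
Unrooted trees are stored with a trifurcating root.
"""

from __future__ import annotations

import dendropy

from .distmatrix import DistanceMatrix
from .errors import ParseError, TreeError


def read_newick(path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"malformed Newick in {path}: {exc}") from exc
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree) + "\n")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def cophenetic(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances.

    Every edge below the root must carry a branch length.
    """
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise TreeError("tree has an edge without a branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    import numpy as np

    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
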
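"""Bipartition extraction and (normalized) Robinson-Foulds distances.

Topological discordance throughout the pipeline is measured as the normalized
Robinson-Foulds (nRF) distance: the size of the symmetric difference between
the two trees' sets of non-trivial bipartitions, divided by the total number
of non-trivial bipartitions in both trees. It ranges from 0 (identical
topologies) to 1 (no shared splits); the denominator convention stays defined
for polytomous trees and equals the usual 2(n-3) for binary trees on n taxa.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import InsufficientOverlapError, TreeIntegrityError, UsageError
from .seqio import leaf_labels

Split = frozenset  # canonical bipartition: the block containing min(taxa)


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, one per internal edge.

    Each split is represented canonically as a frozenset of tip labels: the
    block that contains the lexicographically smallest taxon. Pendant
    (trivial) splits are excluded; polytomies simply yield fewer splits.
    """
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        raise TreeIntegrityError("duplicate tip labels")
    if len(labels) < 4:
        raise UsageError(f"bipartitions require >= 4 tips, got {len(labels)}")
    all_taxa = frozenset(labels)
    anchor = min(all_taxa)
    splits: set[frozenset] = set()
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        block = frozenset().union(*(below[c] for c in node.child_nodes()))
        below[node] = block
        if node.parent_node is None:
            continue  # seed node: no edge above
        if 2 <= len(block) <= len(all_taxa) - 2:
            splits.add(block if anchor in block else all_taxa - block)
    return splits


def _restrict(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    return tree.extract_tree_with_taxa_labels(labels)


def _shared_bipartitions(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[set[frozenset], set[frozenset]]:
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    shared = l1 & l2
    if len(shared) < 4:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared taxa; >= 4 required"
        )
    if l1 != shared:
        t1 = _restrict(t1, shared)
    if l2 != shared:
        t2 = _restrict(t2, shared)
    return bipartitions(t1), bipartitions(t2)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unnormalized Robinson-Foulds distance on the shared taxon set."""
    b1, b2 = _shared_bipartitions(t1, t2)
    return len(b1 ^ b2)


def nrf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Normalized RF: symmetric difference / total split count of both trees.

    Defined as 0 when neither tree has any non-trivial split.
    """
    b1, b2 = _shared_bipartitions(t1, t2)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


def pairwise_nrf_matrix(
    trees: Sequence[dendropy.Tree] | Mapping[str, dendropy.Tree],
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """All-pairs nRF matrix plus the flat upper-triangle distribution.

    Returns a symmetric, zero-diagonal DataFrame indexed by tree labels, and
    the C(n, 2) upper-triangle values in row-major pair order.
    """
    if isinstance(trees, Mapping):
        labels = list(trees)
        tree_list = [trees[k] for k in labels]
    else:
        tree_list = list(trees)
        if labels is None:
            labels = [f"tree{i + 1}" for i in range(len(tree_list))]
    if len(tree_list) < 2:
        raise UsageError("pairwise_nrf_matrix requires >= 2 trees")
    n = len(tree_list)
    mat = np.zeros((n, n))
    flat = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = nrf_distance(tree_list[i], tree_list[j])
            except Exception as exc:
                raise type(exc)(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
            flat.append(d)
    return pd.DataFrame(mat, index=list(labels), columns=list(labels)), np.array(flat)
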
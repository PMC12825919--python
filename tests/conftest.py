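"""Shared fixtures and independent pure-Python tree oracles.

The oracle code below never touches the package's tree machinery: trees are
nested tuples, splits are computed by direct clade collection, and RF is the
symmetric difference of the two split sets. It exists so the package's
bipartition/RF implementation can be checked against something it shares no
code with.
"""

from __future__ import annotations

import numpy as np
import pytest

from gcdiscord.simulate import SyntheticConfig, generate_dataset


# --- nested-tuple tree oracles ----------------------------------------------

def tuple_leaves(t) -> frozenset:
    if isinstance(t, tuple):
        return frozenset().union(*(tuple_leaves(c) for c in t))
    return frozenset([t])


def tuple_splits(t) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree behind a rooted tuple."""
    all_taxa = tuple_leaves(t)
    anchor = min(all_taxa)
    n = len(all_taxa)
    splits: set[frozenset] = set()

    def visit(node):
        if not isinstance(node, tuple):
            return
        block = tuple_leaves(node)
        if 2 <= len(block) <= n - 2:
            splits.add(block if anchor in block else all_taxa - block)
        for child in node:
            visit(child)

    for child in t:
        visit(child)
    return splits


def rf_oracle(t1, t2) -> int:
    return len(tuple_splits(t1) ^ tuple_splits(t2))


def tuple_to_newick(t) -> str:
    def render(node):
        if isinstance(node, tuple):
            return "(" + ",".join(render(c) for c in node) + ")"
        return str(node)

    return render(t) + ";"


def random_topology(labels, rng: np.random.Generator):
    """Random rooted binary tuple by repeated random joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def enumerate_topologies(labels):
    """All (2k-3)!! rooted binary leaf-labeled tuples, by leaf insertion."""

    def insertions(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            left, right = t
            for l2 in insertions(left, leaf):
                yield (l2, right)
            for r2 in insertions(right, leaf):
                yield (left, r2)

    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = [t2 for t in trees for t2 in insertions(t, leaf)]
    return trees


# --- datasets ----------------------------------------------------------------

@pytest.fixture(scope="session")
def study_dataset():
    """The canonical study-scale synthetic dataset (24 taxa, 13+60 genes)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset for fast module-level tests."""
    return generate_dataset(
        SyntheticConfig(n_taxa=12, n_nuclear_genes=16, seed=5)
    )
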
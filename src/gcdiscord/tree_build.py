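"""Desk-scale tree construction: pairwise distances, neighbor joining, and
column-bootstrap supports.

The analysis pipeline is engine-agnostic: any method that turns an amino-acid
alignment into a tree with branch lengths and supports can feed the
comparison and matching stages. The internal engine is distance-based
neighbor joining (p-distance or Poisson-corrected) with nonparametric
bootstrap over alignment columns; an adapter for an external
maximum-likelihood command is provided behind a feature flag.

Neighbor joining here is deterministic: ties in the Q criterion are broken by
the lexicographically smallest pair of cluster keys (a cluster's key is the
smallest taxon label it contains), so the output topology does not depend on
input taxon order.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path

import dendropy
import numpy as np

from .errors import (
    AdapterError,
    MatrixIntegrityError,
    MissingOverlapError,
    UsageError,
)
from .seqio import AA20, Alignment, GeneRecord, write_fasta, read_newick, set_node_support
from .tree_compare import bipartitions


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix (substitutions/site) over taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise MatrixIntegrityError("matrix shape does not match taxon count")
        if not np.isfinite(v).all():
            raise MatrixIntegrityError("non-finite distance entries")
        if not np.allclose(v, v.T):
            raise MatrixIntegrityError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise MatrixIntegrityError("non-zero diagonal")
        if (v < 0).any():
            raise MatrixIntegrityError("negative distances")
        self.values = v


_LUTS = {}
for _alpha, _chars in (("aa", AA20), ("nt", "ACGT")):
    _lut = np.full(256, -1, dtype=np.int8)
    for _i, _c in enumerate(_chars):
        _lut[ord(_c)] = _i
    _LUTS[_alpha] = _lut


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Integer-encode an alignment; gaps/ambiguity/stops map to -1."""
    raw = np.array(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in aln.records.values()]
    )
    return _LUTS[aln.alphabet][raw]


def _p_matrix(enc: np.ndarray, taxa: list[str]) -> np.ndarray:
    """Pairwise uncorrected mismatch fractions with pairwise deletion."""
    n = enc.shape[0]
    valid = enc >= 0
    P = np.zeros((n, n))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        comparable = both.sum(axis=1)
        if (comparable == 0).any():
            j = i + 1 + int(np.argmax(comparable == 0))
            raise MissingOverlapError(
                f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable columns"
            )
        mism = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        P[i, i + 1 :] = mism / comparable
    return P + P.T


def aa_distance_matrix(
    aln: Alignment, model: str = "p", p_cap: float = 0.95
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``model="p"`` gives uncorrected mismatch fractions over pairwise gap-free
    columns; ``model="poisson"`` applies the multiple-hit correction
    ``-ln(1 - p)`` with p capped at ``p_cap`` to keep distances finite.
    """
    if aln.n_taxa < 2:
        raise UsageError("distance matrix requires >= 2 taxa")
    enc = encode_alignment(aln)
    P = _p_matrix(enc, aln.taxa)
    if model == "p":
        D = P
    elif model == "poisson":
        D = -np.log1p(-np.minimum(P, p_cap))
        np.fill_diagonal(D, 0.0)
    else:
        raise UsageError(f"unknown distance model {model!r}")
    return DistanceMatrix(aln.taxa, D)


def patristic_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distances between all tree tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, D)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree.

    Negative branch-length estimates are clamped to zero. The resulting tree
    carries a trifurcating seed node (unrooted convention).
    """
    n0 = len(dm.taxa)
    if n0 < 4:
        raise UsageError(f"neighbor joining requires >= 4 taxa, got {n0}")
    tns = dendropy.TaxonNamespace(sorted(dm.taxa))
    size = 2 * n0  # generous upper bound on cluster slots
    D = np.zeros((size, size))
    D[:n0, :n0] = dm.values
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.taxa
    ]
    keys: list[str] = list(dm.taxa)
    active: list[int] = list(range(n0))
    nxt = n0

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-10 * max(1.0, abs(qmin))
        best = None
        for a, b in np.argwhere(Q <= qmin + tol):
            if a >= b:
                continue
            ka, kb = keys[active[a]], keys[active[b]]
            pair = (ka, kb) if ka < kb else (kb, ka)
            if best is None or pair < best[0]:
                best = (pair, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        others = [k for k in active if k != i and k != j]
        D[nxt, others] = D[others, nxt] = 0.5 * (
            D[i, others] + D[j, others] - dij
        )
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = others + [nxt]
        nxt += 1

    i, j, k = active
    root = dendropy.Node()
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
        root.add_child(nodes[x])
        nodes[x].edge.length = max(lx, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def bootstrap_support(
    aln: Alignment,
    replicates: int = 100,
    seed: int = 0,
    model: str = "p",
    p_cap: float = 0.95,
) -> dendropy.Tree:
    """NJ tree on the full alignment, internal nodes annotated with the
    percentage of column-bootstrap replicate trees containing each split."""
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    enc = encode_alignment(aln)
    taxa = aln.taxa

    def _tree_from(enc_cols: np.ndarray) -> dendropy.Tree:
        P = _p_matrix(enc_cols, taxa)
        if model == "poisson":
            P = -np.log1p(-np.minimum(P, p_cap))
            np.fill_diagonal(P, 0.0)
        return nj_tree(DistanceMatrix(taxa, P))

    main = _tree_from(enc)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    L = enc.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        try:
            rep_tree = _tree_from(enc[:, cols])
        except MissingOverlapError:
            continue  # resample dropped all comparable columns for a pair
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1

    all_taxa = frozenset(taxa)
    anchor = min(all_taxa)
    below: dict[dendropy.Node, frozenset] = {}
    for node in main.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        block = frozenset().union(*(below[c] for c in node.child_nodes()))
        below[node] = block
        if node.parent_node is None:
            continue
        if 2 <= len(block) <= len(all_taxa) - 2:
            split = block if anchor in block else all_taxa - block
            set_node_support(node, 100.0 * counts.get(split, 0) / replicates)
    return main


@dataclass
class TreeBuildConfig:
    """Configuration for :func:`build_gene_tree`.

    ``bootstrap=0`` skips support estimation (topology and branch lengths
    only). The ``external`` engine shells out to ``ml_command``, a template
    with ``{aln}`` and ``{out}`` placeholders, and reads ``{out}.treefile``.
    """

    engine: str = "nj"  # "nj" | "external"
    model: str = "poisson"
    bootstrap: int = 100
    seed: int = 0
    p_cap: float = 0.95
    ml_command: str | None = None

    def with_seed(self, seed: int) -> "TreeBuildConfig":
        return replace(self, seed=seed)


def build_gene_tree(
    gene: GeneRecord, cfg: TreeBuildConfig | None = None
) -> dendropy.Tree:
    """Build a tree for one gene's amino-acid alignment."""
    cfg = cfg or TreeBuildConfig()
    if cfg.engine == "external":
        return _external_tree(gene, cfg)
    if cfg.engine != "nj":
        raise UsageError(f"unknown engine {cfg.engine!r}")
    if cfg.bootstrap > 0:
        return bootstrap_support(
            gene.aa, cfg.bootstrap, cfg.seed, model=cfg.model, p_cap=cfg.p_cap
        )
    return nj_tree(aa_distance_matrix(gene.aa, model=cfg.model, p_cap=cfg.p_cap))


def _external_tree(gene: GeneRecord, cfg: TreeBuildConfig) -> dendropy.Tree:
    if not cfg.ml_command:
        raise AdapterError("external engine selected but no ml_command configured")
    with tempfile.TemporaryDirectory(prefix="gcdiscord-ml-") as tmp:
        aln_path = Path(tmp) / f"{gene.gene_id}.faa"
        out_prefix = Path(tmp) / gene.gene_id
        write_fasta(gene.aa, aln_path)
        cmd = cfg.ml_command.format(aln=str(aln_path), out=str(out_prefix))
        try:
            proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        except OSError as exc:
            raise AdapterError(f"cannot run external command {cmd!r}: {exc}") from exc
        if proc.returncode != 0:
            raise AdapterError(
                f"external command failed (exit {proc.returncode}): {cmd}\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        tree_file = Path(f"{out_prefix}.treefile")
        if not tree_file.exists():
            raise AdapterError(f"external command produced no {tree_file}")
        return read_newick(tree_file)
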
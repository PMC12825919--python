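"""Per-gene property metrics.

Nine properties are computed for every gene, mirroring the quantities used to
screen for drivers of mito-nuclear discordance:

(a) alignment length (amino-acid sites), (b) GC content, (c) amino-acid
substitution saturation, (d) effective number of amino acids, (e) proportion
of constant sites, (f) proportion of parsimony-informative sites, (g) median
external branch length, (h) mean bootstrap support, (i) treeness.

Composition metrics pool residues over all sequences; gaps and ambiguity
codes (N for nucleotides, X for amino acids) are excluded from both numerator
and denominator. Codon-position GC (GC1/GC2/GC3) and the 20-amino-acid usage
spectrum are computed alongside for compositional-bias diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateTreeError,
    FrameError,
    MissingSupportError,
    UndefinedCompositionError,
    UsageError,
)
from .seqio import AA20, Alignment, GeneRecord, leaf_labels, node_support
from .tree_build import encode_alignment, patristic_distance_matrix, _p_matrix


@dataclass
class GeneProperties:
    """The nine per-gene metrics (GC fields are None when no CDS exists)."""

    alignment_length: int
    gc_content: float | None
    saturation: float
    enaa: float
    prop_constant: float
    prop_informative: float
    ext_branch_median: float
    mean_bootstrap: float
    treeness: float
    gc1: float | None = None
    gc2: float | None = None
    gc3: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CodonPositionGC:
    gc1: float
    gc2: float
    gc3: float


# --- nucleotide composition --------------------------------------------------

def _gc_counts(alignment: Alignment, columns: slice | np.ndarray | None = None):
    if alignment.alphabet != "nt":
        raise UsageError("gc_content expects a nucleotide alignment")
    mat = alignment.matrix()
    if columns is not None:
        mat = mat[:, columns]
    gc = np.isin(mat, list("GC")).sum()
    acgt = np.isin(mat, list("ACGT")).sum()
    return int(gc), int(acgt)


def gc_content(alignment: Alignment) -> float:
    """Pooled (G+C)/(A+C+G+T) over all sequences; gaps and N excluded."""
    gc, acgt = _gc_counts(alignment)
    if acgt == 0:
        raise UndefinedCompositionError("no unambiguous nucleotides")
    return gc / acgt


def gc_by_codon_position(cds: Alignment) -> CodonPositionGC:
    """GC content restricted to first, second and third codon positions."""
    if cds.length % 3 != 0:
        raise FrameError(f"CDS alignment length {cds.length} not divisible by 3")
    out = []
    for offset in range(3):
        gc, acgt = _gc_counts(cds, np.arange(offset, cds.length, 3))
        if acgt == 0:
            raise UndefinedCompositionError(
                f"no unambiguous nucleotides at codon position {offset + 1}"
            )
        out.append(gc / acgt)
    return CodonPositionGC(*out)


# --- amino-acid composition --------------------------------------------------

def aa_usage(aa: Alignment) -> pd.Series:
    """Pooled frequencies of the 20 standard amino acids (sums to 1)."""
    if aa.alphabet != "aa":
        raise UsageError("aa_usage expects an amino-acid alignment")
    mat = aa.matrix()
    counts = pd.Series(
        {res: int((mat == res).sum()) for res in AA20}, name="frequency"
    )
    total = counts.sum()
    if total == 0:
        raise UndefinedCompositionError("no countable residues")
    return counts / total


def _countable_matrix(aa: Alignment) -> np.ndarray:
    """Integer codes (n_taxa, length); gaps/X/stop coded -1."""
    return encode_alignment(aa)


def prop_constant_sites(aa: Alignment) -> float:
    """Fraction of columns whose non-gap unambiguous residues are all equal.

    All-gap columns count as constant, matching the convention of ML-software
    log summaries.
    """
    if aa.n_taxa < 2:
        raise UsageError("constant-site proportion requires >= 2 sequences")
    if aa.length == 0:
        raise UsageError("zero-length alignment")
    enc = _countable_matrix(aa)
    masked = np.where(enc >= 0, enc, np.iinfo(np.int8).max)
    cmin = masked.min(axis=0)
    cmax = np.where(enc >= 0, enc, np.iinfo(np.int8).min).max(axis=0)
    constant = (cmin >= cmax)  # <= one distinct state (all-gap: min > max)
    return float(constant.mean())


def prop_parsimony_informative(aa: Alignment) -> float:
    """Fraction of columns with >= 2 states each occurring >= 2 times."""
    if aa.n_taxa < 4:
        raise UsageError("parsimony-informative proportion requires >= 4 sequences")
    if aa.length == 0:
        raise UsageError("zero-length alignment")
    enc = _countable_matrix(aa)
    n_states = 21
    informative = np.zeros(aa.length, dtype=bool)
    counts = np.zeros((n_states, aa.length), dtype=np.int32)
    for s in range(n_states - 1):
        counts[s] = (enc == s).sum(axis=0)
    informative = (counts >= 2).sum(axis=0) >= 2
    return float(informative.mean())


def effective_number_of_aa(aa: Alignment) -> float:
    """Mean per-column exponential Shannon entropy of residue frequencies.

    1.0 when a single amino acid is used exclusively; 20.0 when all twenty
    are uniformly distributed. Columns without countable residues are skipped.
    """
    enc = _countable_matrix(aa)
    counts = np.stack([(enc == s).sum(axis=0) for s in range(20)])
    totals = counts.sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise UndefinedCompositionError("no countable columns")
    p = counts[:, keep] / totals[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ent = -plogp.sum(axis=0)
    return float(np.exp(ent).mean())


# --- tree-based metrics ------------------------------------------------------

def saturation(aa: Alignment, gene_tree: dendropy.Tree) -> float:
    """Substitution-saturation statistic in [0, 1].

    Slope of the zero-intercept least-squares fit of pairwise uncorrected
    p-distance on pairwise patristic distance; 1 means distances accumulate
    linearly (minimal saturation), values near 0 mean heavy saturation.
    """
    tips = set(leaf_labels(gene_tree))
    missing = tips - set(aa.taxa)
    if missing:
        raise UsageError(f"tree tips missing from alignment: {sorted(missing)[:5]}")
    if len(tips) < 4:
        raise UsageError("saturation requires >= 4 shared taxa")
    pat = patristic_distance_matrix(gene_tree)
    sub = aa.subset(pat.taxa)
    P = _p_matrix(encode_alignment(sub), pat.taxa)
    iu = np.triu_indices(len(pat.taxa), k=1)
    x = pat.values[iu]
    y = P[iu]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateTreeError("all patristic distances are zero")
    slope = float(np.dot(x, y)) / sxx
    return min(max(slope, 0.0), 1.0)


def _unrooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()
    return t


def treeness(tree: dendropy.Tree) -> float:
    """Internal branch length over total branch length, on the unrooted tree."""
    if len(leaf_labels(tree)) < 4:
        raise UsageError("treeness requires >= 4 tips")
    t = _unrooted_copy(tree)
    internal = total = 0.0
    for edge in t.preorder_edge_iter():
        if edge.tail_node is None or edge.length is None:
            continue
        total += edge.length
        if edge.head_node.is_internal():
            internal += edge.length
    if total <= 0:
        raise DegenerateTreeError("zero total branch length")
    return internal / total


def median_external_branch_length(tree: dendropy.Tree) -> float:
    """Median pendant-edge length (even tip counts: mean of middle two)."""
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise UsageError("median external branch length requires >= 2 tips")
    return float(np.median([lf.edge.length or 0.0 for lf in leaves]))


def mean_bootstrap(tree: dendropy.Tree) -> float:
    """Mean support over internal nodes carrying support values."""
    vals = [
        s
        for node in tree.preorder_internal_node_iter()
        if node.parent_node is not None
        for s in [node_support(node)]
        if s is not None
    ]
    if not vals:
        raise MissingSupportError("no internal node carries a support value")
    return float(np.mean(vals))


# --- aggregation -------------------------------------------------------------

PROPERTY_NAMES = [
    "alignment_length",
    "gc_content",
    "saturation",
    "enaa",
    "prop_constant",
    "prop_informative",
    "ext_branch_median",
    "mean_bootstrap",
    "treeness",
]

TABLE_COLUMNS = ["gene_id", "source", "alignment_length", "gc_content", "gc1",
                 "gc2", "gc3", "saturation", "enaa", "prop_constant",
                 "prop_informative", "ext_branch_median", "mean_bootstrap",
                 "treeness"]


def compute_all_properties(
    gene: GeneRecord, tree: dendropy.Tree
) -> GeneProperties:
    """All nine metrics for one gene (plus GC1/GC2/GC3 when a CDS exists)."""
    try:
        gc = gc123 = None
        if gene.cds is not None:
            gc = gc_content(gene.cds)
            gc123 = gc_by_codon_position(gene.cds)
        return GeneProperties(
            alignment_length=gene.aa.length,
            gc_content=gc,
            gc1=gc123.gc1 if gc123 else None,
            gc2=gc123.gc2 if gc123 else None,
            gc3=gc123.gc3 if gc123 else None,
            saturation=saturation(gene.aa, tree),
            enaa=effective_number_of_aa(gene.aa),
            prop_constant=prop_constant_sites(gene.aa),
            prop_informative=prop_parsimony_informative(gene.aa),
            ext_branch_median=median_external_branch_length(tree),
            mean_bootstrap=mean_bootstrap(tree),
            treeness=treeness(tree),
        )
    except Exception as exc:
        raise type(exc)(f"gene {gene.gene_id}: {exc}") from exc


def properties_table(
    genes: Mapping[str, GeneRecord], trees: Mapping[str, dendropy.Tree]
) -> pd.DataFrame:
    """Per-gene properties as a tidy table (one row per gene)."""
    rows = []
    for gene_id, gene in genes.items():
        props = compute_all_properties(gene, trees[gene_id])
        row = {"gene_id": gene_id, "source": gene.source}
        row.update(props.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
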
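"""Synthetic datasets with GC-coupled gene-tree discordance.

The generator emulates the statistical structure of a phylogenomic dataset
in which a small set of AT-rich mitochondrial protein-coding genes
(invertebrate mitochondrial code, short alignments) coexists with a large
set of nuclear single-copy genes (standard code, GC roughly 38-48%), and in
which the topological discordance of a gene's tree from the species tree
rises with its GC content.

The causal chain is explicit and minimal:

1. a pure-birth species tree is simulated and scaled to unit mean
   root-to-tip depth;
2. each gene receives its own tree: the species tree perturbed by a number
   of nearest-neighbor-interchange (NNI) moves that grows linearly with the
   gene's GC target (slope ``kappa``) — this is the single discordance
   knob. Half of a gene's moves (floor(m/2)) follow a dataset-wide shared
   NNI trajectory, so high-GC genes are pulled toward a common conflicting
   topology (the signature expected from GC-biased gene conversion); the
   remaining moves are gene-specific random NNIs, so genes of equal GC
   still disagree with each other;
3. amino-acid sequences evolve on the gene tree under an equal-exchange,
   composition-stationary model whose stationary frequencies interpolate
   between a low-GC-codon amino-acid set (F, I, K, L, M, N, Y) and a
   high-GC set (A, G, P, R, W);
4. coding sequences are obtained by synonymous back-translation whose
   third-position GC preference is calibrated per gene (by bisection) so the
   realized overall GC matches the gene's target.

Everything is driven by one seed; identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import ConfigurationError, EncodingError, UsageError
from .seqio import (
    AA20,
    Alignment,
    GeneRecord,
    META_COLUMNS,
    write_fasta,
    write_newick,
)

#: Amino acids whose codons are AT-rich (favored in low-GC genes)
LOW_GC_AA = "FIKLMNY"
#: Amino acids whose codons are GC-rich (favored in high-GC genes)
HIGH_GC_AA = "AGPRW"

#: The 13 protein-coding genes of a typical animal mitochondrial genome.
MITO_GENE_NAMES = [
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale analog of a large insect phylogenomic
    dataset: 13 short AT-rich mitochondrial genes and a nuclear gene pool
    with GC ~ Normal(0.43, 0.03), with gene-tree discordance coupled to GC
    through ``kappa`` (maximum NNI moves across the GC range; 0 = no
    coupling, the null model).
    """

    n_taxa: int = 24
    n_mito_genes: int = 13
    n_nuclear_genes: int = 60
    nuclear_gc_mean: float = 0.43
    nuclear_gc_sd: float = 0.03
    nuclear_gc_clip: tuple[float, float] = (0.36, 0.50)
    mito_gc: float = 0.25
    mito_length_range: tuple[int, int] = (100, 350)  # codons
    nuclear_length_range: tuple[int, int] = (100, 350)  # codons
    kappa: float = 6.0
    mito_tree_moves: int = 1
    rate: float = 0.5  # expected substitutions/site per unit branch length
    min_internal_branch: float = 0.02  # fraction of tree depth
    beta: float = 2.0  # back-translation GC3 bias strength
    aa_bias: float = 3.0  # amino-acid composition bias strength
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 8:
            raise ConfigurationError("n_taxa must be >= 8")
        lo, hi = self.nuclear_gc_clip
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("nuclear_gc_clip must satisfy 0 < lo < hi < 1")
        if not (0.0 < self.mito_gc < 1.0):
            raise ConfigurationError("mito_gc must lie in (0, 1)")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        for name, (a, b) in (
            ("mito_length_range", self.mito_length_range),
            ("nuclear_length_range", self.nuclear_length_range),
        ):
            if a < 30 or b < a:
                raise ConfigurationError(f"{name} must satisfy 30 <= lo <= hi")


# --- species tree ------------------------------------------------------------

def simulate_species_tree(
    n_taxa: int,
    rng: np.random.Generator,
    min_internal_branch: float = 0.0,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree scaled to mean root-to-tip depth 1.0.

    Tips are labeled T01, T02, ... in order of appearance. With
    ``min_internal_branch > 0``, internal branches shorter than that fraction
    of the tree depth are raised to it before the final normalization, so
    every speciation event is separated by a resolvable amount of evolution
    (Yule trees otherwise produce near-zero recent internal edges that no
    desk-scale amount of sequence can recover).
    """
    if n_taxa < 4:
        raise UsageError("species tree requires >= 4 taxa")
    # birth times of lineage splits; lineages tracked as (birth_time, id)
    births: dict[int, float] = {0: 0.0, 1: 0.0}
    children: dict[int, tuple[int, int]] = {}
    active = [0, 1]
    nxt = 2
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        lineage = active.pop(k)
        a, b = nxt, nxt + 1
        nxt += 2
        births[a] = births[b] = t
        children[lineage] = (a, b)
        active.extend([a, b])
    t += rng.exponential(1.0 / n_taxa)  # extend tips to the next event time
    depth = t if t > 0 else 1.0

    width = max(2, len(str(n_taxa)))
    labels = {lid: f"T{i + 1:0{width}d}" for i, lid in enumerate(sorted(active))}
    tns = dendropy.TaxonNamespace(sorted(labels.values()))

    def build(lid: int) -> dendropy.Node:
        # lineage lid lives from births[lid] until it splits (or until t)
        if lid in children:
            node = dendropy.Node()
            for c in children[lid]:
                node.add_child(build(c))
            node.edge.length = (births[children[lid][0]] - births[lid]) / depth
        else:
            node = dendropy.Node(taxon=tns.get_taxon(labels[lid]))
            node.edge.length = (t - births[lid]) / depth
        return node

    root = dendropy.Node()
    for lid in (0, 1):
        root.add_child(build(lid))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    if min_internal_branch > 0:
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.is_internal():
                node.edge.length = max(node.edge.length, min_internal_branch)
    # normalize to mean root-to-tip depth exactly 1.0
    depths = []
    for leaf in tree.leaf_node_iter():
        d, nd = 0.0, leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    scale = float(np.mean(depths))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.edge.length or 0.0) / scale
    return tree


def perturb_topology(
    tree: dendropy.Tree, n_moves: int, rng: np.random.Generator
) -> dendropy.Tree:
    """Apply ``n_moves`` random NNI moves; branch lengths travel with subtrees."""
    if n_moves < 0:
        raise UsageError("n_moves must be >= 0")
    t = tree.clone(depth=1)
    for _ in range(n_moves):
        candidates = [
            nd
            for nd in t.preorder_internal_node_iter()
            if nd.parent_node is not None
        ]
        if not candidates:
            break
        v = candidates[int(rng.integers(len(candidates)))]
        u = v.parent_node
        siblings = [c for c in u.child_nodes() if c is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        vc = v.child_nodes()
        c = vc[int(rng.integers(len(vc)))]
        # swap subtree c (below v) with sibling s (below u)
        v.remove_child(c)
        u.remove_child(s)
        v.add_child(s)
        u.add_child(c)
    return t


# --- sequence evolution ------------------------------------------------------

def stationary_frequencies(theta: float, aa_bias: float = 3.0) -> np.ndarray:
    """Amino-acid stationary frequencies interpolating between a low-GC-codon
    composition (theta=0) and a high-GC-codon composition (theta=1)."""
    if not 0.0 <= theta <= 1.0:
        raise UsageError("theta must lie in [0, 1]")
    w = np.ones(20)
    for i, aa in enumerate(AA20):
        if aa in LOW_GC_AA:
            w[i] += aa_bias * (1.0 - theta)
        elif aa in HIGH_GC_AA:
            w[i] += aa_bias * theta
    return w / w.sum()


def evolve_aa(
    tree: dendropy.Tree,
    n_sites: int,
    theta: float,
    rate: float,
    rng: np.random.Generator,
    aa_bias: float = 3.0,
) -> Alignment:
    """Evolve amino-acid sequences on ``tree`` under an equal-exchange,
    composition-stationary model (F81-like on 20 states).

    Along a branch of length b each site independently keeps its state with
    probability exp(-mu*b) and otherwise redraws from the stationary
    frequencies, with mu scaled so ``rate`` is the expected number of
    substitutions per site per unit branch length.
    """
    if n_sites < 1:
        raise UsageError("n_sites must be >= 1")
    pi = stationary_frequencies(theta, aa_bias)
    homo = float(np.dot(pi, pi))
    mu = rate / (1.0 - homo) if rate > 0 else 0.0
    states: dict[dendropy.Node, np.ndarray] = {}
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.choice(20, size=n_sites, p=pi)
        else:
            parent = states[node.parent_node]
            b = node.edge.length or 0.0
            if mu > 0 and b > 0:
                redraw = rng.random(n_sites) >= np.exp(-mu * b)
                seq = parent.copy()
                k = int(redraw.sum())
                if k:
                    seq[redraw] = rng.choice(20, size=k, p=pi)
            else:
                seq = parent.copy()
        states[node] = seq
        if node.is_leaf():
            seqs[node.taxon.label] = seq
    aa_arr = np.array(list(AA20))
    return Alignment(
        {t: "".join(aa_arr[s]) for t, s in sorted(seqs.items())}, "aa"
    )


# --- back-translation --------------------------------------------------------

def _codon_options(code_id: int) -> dict[str, list[tuple[str, int, int]]]:
    """aa -> [(codon, #GC bases, GC3 flag)] for a genetic code (stops excluded)."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    out: dict[str, list[tuple[str, int, int]]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        gc = sum(b in "GC" for b in codon)
        gc3 = 1 if codon[2] in "GC" else 0
        out.setdefault(aa, []).append((codon, gc, gc3))
    return out


def expected_gc(
    aa_counts: dict[str, int], code_id: int, beta: float, gc3_target: float
) -> float:
    """Expected overall GC of a back-translated sequence with pooled residue
    counts ``aa_counts`` under the beta-weighted synonymous codon choice."""
    options = _codon_options(code_id)
    num = den = 0.0
    for aa, count in aa_counts.items():
        if count == 0:
            continue
        opts = options.get(aa)
        if not opts:
            raise EncodingError(f"residue {aa!r} has no codon in code {code_id}")
        w = np.array([np.exp(beta * (1.0 - abs(gc3 - gc3_target))) for _, _, gc3 in opts])
        gc = np.array([g for _, g, _ in opts])
        num += count * float(np.dot(w, gc) / w.sum())
        den += count * 3.0
    return num / den


def calibrate_gc3_target(
    aa_counts: dict[str, int],
    code_id: int,
    beta: float,
    target_gc: float,
    tol: float = 1e-6,
) -> float:
    """Bisection for the GC3 preference that realizes ``target_gc`` overall.

    Clamped to [0, 1] when the target is outside the achievable range.
    """
    lo, hi = 0.0, 1.0
    if expected_gc(aa_counts, code_id, beta, lo) >= target_gc:
        return lo
    if expected_gc(aa_counts, code_id, beta, hi) <= target_gc:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_gc(aa_counts, code_id, beta, mid) < target_gc:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def back_translate(
    aa: Alignment,
    code_id: int,
    beta: float,
    gc3_target: float,
    rng: np.random.Generator,
) -> Alignment:
    """Replace each residue by a synonymous codon of the genetic code, drawn
    with probability proportional to exp(beta*(1 - |GC3(codon) - gc3_target|)).

    Gaps become the all-gap codon; no stop codons are ever emitted, so
    translating the result reproduces the input amino acids exactly.
    """
    if aa.alphabet != "aa":
        raise UsageError("back_translate expects an amino-acid alignment")
    options = _codon_options(code_id)
    probs: dict[str, tuple[list[str], np.ndarray]] = {}
    for res, opts in options.items():
        w = np.array([np.exp(beta * (1.0 - abs(gc3 - gc3_target))) for _, _, gc3 in opts])
        probs[res] = ([c for c, _, _ in opts], w / w.sum())
    records = {}
    for taxon, seq in aa.records.items():
        arr = np.array(list(seq), dtype="U1")
        out = np.empty(len(arr), dtype="U3")
        out[arr == "-"] = "---"
        for res in sorted(set(seq) - {"-"}):  # sorted: deterministic draws
            if res not in probs:
                raise EncodingError(
                    f"residue {res!r} (taxon {taxon}) has no codon in code {code_id}"
                )
            codon_list, p = probs[res]
            idx = np.where(arr == res)[0]
            draws = rng.choice(len(codon_list), size=len(idx), p=p)
            out[idx] = np.array(codon_list, dtype="U3")[draws]
        records[taxon] = "".join(out)
    return Alignment(records, "nt")


# --- dataset assembly --------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A generated dataset: reference tree, gene records, true gene trees."""

    config: SyntheticConfig
    reference: dendropy.Tree
    records: dict[str, GeneRecord]
    gene_trees: dict[str, dendropy.Tree]
    gene_info: pd.DataFrame  # gene_id, source, target_gc, theta, n_moves, length


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _balanced_assignment(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pair the drawn values of a null covariate ``y`` to items ranked by
    ``x`` with a low-discrepancy stride, so that any contiguous window of
    ``y`` values contains an even spread of ``x`` ranks.

    This is a Latin-square-style balance: the marginal distributions of both
    variables are exactly the drawn ones, but finite-sample confounding
    between them (which would make a designed-null covariate spuriously
    informative) is suppressed by construction.
    """
    import math

    n = len(x)
    k = max(1, int(round(0.618 * n)))
    while math.gcd(k, n) != 1:
        k += 1
    x_order = np.argsort(x, kind="stable")
    y_sorted = np.sort(y)
    out = np.empty(n, dtype=y.dtype)
    for g in range(n):
        out[x_order[g]] = y_sorted[(g * k) % n]
    return out


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset under ``cfg`` (deterministic given cfg.seed)."""
    cfg.validate()
    reference = simulate_species_tree(
        cfg.n_taxa, _rng(cfg.seed, 0), cfg.min_internal_branch
    )
    lo, hi = cfg.nuclear_gc_clip

    # shared discordance trajectory: cumulative NNI perturbations of the
    # reference; gene i starts from stage floor(m_i / 2) of this walk, so
    # high-GC genes share a common conflicting backbone
    max_shared = max(1, 3 * int(np.ceil(cfg.kappa)))
    traj_rng = _rng(cfg.seed, 3)
    trajectory = [reference]
    for _ in range(max_shared):
        trajectory.append(perturb_topology(trajectory[-1], 1, traj_rng))

    records: dict[str, GeneRecord] = {}
    gene_trees: dict[str, dendropy.Tree] = {}
    info_rows = []

    # mitochondrial genes: AT-rich, invertebrate mitochondrial code, short
    if cfg.n_mito_genes <= len(MITO_GENE_NAMES):
        mito_ids = MITO_GENE_NAMES[: cfg.n_mito_genes]
    else:
        mito_ids = MITO_GENE_NAMES + [
            f"mt{i + 1:02d}" for i in range(cfg.n_mito_genes - len(MITO_GENE_NAMES))
        ]
    for i, gene_id in enumerate(mito_ids):
        rng = _rng(cfg.seed, 1, i)
        length = int(
            rng.integers(cfg.mito_length_range[0], cfg.mito_length_range[1] + 1)
        )
        _make_gene(
            gene_id, "mito", 5, cfg.mito_gc, 0.0, 0, cfg.mito_tree_moves,
            length, cfg, trajectory, rng, records, gene_trees, info_rows,
        )

    # nuclear genes: GC drawn from the configured distribution, coupled moves.
    # Lengths are drawn separately and assigned so the realized GC-length
    # rank correlation is ~0 (balanced assignment): alignment length is the
    # designed-null property and must not be confounded with GC by sampling
    # accident in a finite gene set.
    n_nuc = cfg.n_nuclear_genes
    draw_rng = _rng(cfg.seed, 4)
    gcs = np.clip(
        draw_rng.normal(cfg.nuclear_gc_mean, cfg.nuclear_gc_sd, size=n_nuc), lo, hi
    )
    lengths = draw_rng.integers(
        cfg.nuclear_length_range[0], cfg.nuclear_length_range[1] + 1, size=n_nuc
    )
    lengths = _balanced_assignment(gcs, lengths)
    for i in range(n_nuc):
        gene_id = f"nuc{i + 1:04d}"
        rng = _rng(cfg.seed, 2, i)
        gc = float(gcs[i])
        theta = (gc - lo) / (hi - lo)
        n_moves = int(round(cfg.kappa * theta))
        # mildly discordant genes (m <= 2) perturb only idiosyncratically;
        # beyond that, discordance also tracks the shared trajectory, three
        # stages per additional move
        shared = 3 * max(0, n_moves - 2)
        _make_gene(
            gene_id, "nuclear", 1, gc, theta, shared, n_moves,
            int(lengths[i]), cfg, trajectory, rng, records, gene_trees,
            info_rows,
        )

    info = pd.DataFrame(
        info_rows,
        columns=["gene_id", "source", "genetic_code", "length_codons",
                 "target_gc", "theta", "n_moves", "shared_moves",
                 "specific_moves"],
    )
    return SyntheticDataset(cfg, reference, records, gene_trees, info)


def _make_gene(
    gene_id: str,
    source: str,
    code_id: int,
    target_gc: float,
    theta: float,
    shared_moves: int,
    specific_moves: int,
    length: int,
    cfg: SyntheticConfig,
    trajectory: list[dendropy.Tree],
    rng: np.random.Generator,
    records: dict,
    gene_trees: dict,
    info_rows: list,
) -> None:
    base = trajectory[min(shared_moves, len(trajectory) - 1)]
    tree = perturb_topology(base, specific_moves, rng)
    aa = evolve_aa(tree, length, theta, cfg.rate, rng, aa_bias=cfg.aa_bias)
    counts = {res: sum(s.count(res) for s in aa.records.values()) for res in AA20}
    g3 = calibrate_gc3_target(counts, code_id, cfg.beta, target_gc)
    cds = back_translate(aa, code_id, cfg.beta, g3, rng)
    records[gene_id] = GeneRecord(
        gene_id=gene_id, source=source, aa=aa, cds=cds, genetic_code=code_id
    )
    gene_trees[gene_id] = tree
    info_rows.append(
        [gene_id, source, code_id, length, target_gc, theta,
         shared_moves + specific_moves, shared_moves, specific_moves]
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write reference.nwk, genes/<id>.faa|.fna, genetrees/<id>.nwk and
    meta.tsv under ``outdir``; returns the path to meta.tsv.

    The full configuration (including the seed) is echoed into
    ``sim_config.txt`` for provenance.
    """
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    (outdir / "genetrees").mkdir(parents=True, exist_ok=True)
    write_newick(ds.reference, outdir / "reference.nwk")
    rows = []
    for gene_id, rec in ds.records.items():
        write_fasta(rec.aa, outdir / "genes" / f"{gene_id}.faa")
        write_fasta(rec.cds, outdir / "genes" / f"{gene_id}.fna")
        write_newick(ds.gene_trees[gene_id], outdir / "genetrees" / f"{gene_id}.nwk")
        rows.append(
            {
                "gene_id": gene_id,
                "source": rec.source,
                "genetic_code": rec.genetic_code,
                "cds_path": f"genes/{gene_id}.fna",
                "aa_path": f"genes/{gene_id}.faa",
                "tree_path": f"genetrees/{gene_id}.nwk",
            }
        )
    meta = outdir / "meta.tsv"
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta, sep="\t", index=False)
    cfg_lines = [f"{k}={v}" for k, v in asdict(ds.config).items()]
    (outdir / "sim_config.txt").write_text("\n".join(cfg_lines) + "\n")
    ds.gene_info.to_csv(outdir / "gene_info.tsv", sep="\t", index=False)
    return meta
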
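"""Sequence, alignment and tree I/O plus genetic-code-aware translation.

The pipeline works on trimmed per-gene multiple sequence alignments (FASTA),
gene trees and concatenation trees (Newick with bootstrap supports encoded as
internal-node labels, the common ML-tool dialect), and a tab-separated gene
metadata table. Trees are represented as :class:`dendropy.Tree` objects
throughout the package; alignments as the lightweight :class:`Alignment`
container below.

Two genetic codes are supported: the standard nuclear code (NCBI table 1) and
the invertebrate mitochondrial code (NCBI table 5), in which ATA encodes Met,
AGA/AGG encode Ser and TGA encodes Trp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    FormatError,
    FrameError,
    NewickParseError,
    TreeIntegrityError,
    UnsupportedCodeError,
    UsageError,
)

#: The twenty standard amino acids, in the conventional alphabetical order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_ALPHABET_CHARS = {
    "nt": frozenset("ACGTN-"),
    "aa": frozenset(AA20) | frozenset("X-*"),
}

#: Characters excluded from composition counts (gaps, ambiguity, stops).
NON_COUNTABLE = frozenset("-NX*")

SUPPORTED_CODES = (1, 5)


@dataclass
class Alignment:
    """An equal-length sequence matrix over a declared alphabet.

    Parameters
    ----------
    records:
        Ordered mapping of taxon id -> sequence string (upper case).
    alphabet:
        ``"nt"`` for nucleotide or ``"aa"`` for amino acid.
    """

    records: dict[str, str]
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABET_CHARS:
            raise UsageError(f"unknown alphabet {self.alphabet!r}; expected 'nt' or 'aa'")
        if not self.records:
            raise UsageError("alignment must contain at least one sequence")
        allowed = _ALPHABET_CHARS[self.alphabet]
        length = None
        for taxon, seq in self.records.items():
            if not taxon:
                raise FormatError("empty taxon id")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentShapeError(
                    f"ragged alignment: taxon {taxon!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            bad = set(seq) - allowed
            if bad:
                site = next(i for i, c in enumerate(seq) if c in bad)
                raise AlphabetError(
                    f"illegal character {seq[site]!r} for alphabet "
                    f"{self.alphabet!r} in taxon {taxon!r} at site {site}"
                )

    @property
    def length(self) -> int:
        """Number of columns (amino-acid sites for ``aa`` alignments)."""
        return len(next(iter(self.records.values())))

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    @property
    def taxa(self) -> list[str]:
        return list(self.records)

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n_taxa, length) array of 1-char strings."""
        return np.array([list(s) for s in self.records.values()], dtype="U1")

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        """Alignment restricted to ``taxa``, in the given order."""
        missing = [t for t in taxa if t not in self.records]
        if missing:
            raise UsageError(f"taxa not in alignment: {missing}")
        return Alignment({t: self.records[t] for t in taxa}, self.alphabet)


def read_fasta(path: str | Path, alphabet: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are case-folded to upper case; original record order is kept.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate taxon id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Alignment(records, alphabet)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment in FASTA (one record per taxon, original order)."""
    recs = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in alignment.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# --- Newick ------------------------------------------------------------------

def _validate_tree(tree: dendropy.Tree) -> None:
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        raise TreeIntegrityError("duplicate tip labels in tree")
    if any(not lab for lab in labels):
        raise TreeIntegrityError("empty tip label in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeIntegrityError(f"negative branch length {edge.length}")
    for node in tree.preorder_internal_node_iter():
        s = node_support(node)
        if s is not None and not (0.0 <= s <= 100.0):
            raise TreeIntegrityError(f"support value {s} outside [0, 100]")


def read_newick(source: str | Path, *, data: str | None = None) -> dendropy.Tree:
    """Read a single Newick tree.

    Internal-node labels that parse as numbers are interpreted as bootstrap
    supports in [0, 100] (the common ML-output dialect); non-numeric labels
    are kept as node names. Underscores in labels are preserved literally.
    """
    try:
        if data is not None:
            tree = dendropy.Tree.get(
                data=data, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickParseError(f"cannot parse Newick from {source!r}: {exc}") from exc
    _validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree in Newick, supports as internal labels.

    Whitespace in taxon labels is normalized to underscores on write.
    """
    Path(path).write_text(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    # dendropy quotes labels containing whitespace; normalize to underscores
    if "'" in s:
        for taxon in tree.taxon_namespace:
            if any(ch.isspace() for ch in taxon.label):
                s = s.replace(f"'{taxon.label}'", taxon.label.replace(" ", "_"))
    return s


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]


def node_support(node: dendropy.Node) -> float | None:
    """Bootstrap support of an internal node, or None if it carries none."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def set_node_support(node: dendropy.Node, value: float) -> None:
    node.label = f"{value:.6g}"


# --- translation -------------------------------------------------------------

def _codon_map(code_id: int) -> dict[str, str]:
    if code_id not in SUPPORTED_CODES:
        raise UnsupportedCodeError(
            f"unsupported genetic code {code_id}; supported: {SUPPORTED_CODES}"
        )
    table = CodonTable.unambiguous_dna_by_id[code_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate_cds(sequence: str, code_id: int) -> str:
    """Translate an in-frame CDS under NCBI genetic code 1 or 5.

    Rules: the all-gap codon ``---`` becomes ``-``; codons containing N or a
    partial gap become ``X`` (partial gaps additionally warn); stop codons are
    rendered ``*`` with a warning when internal.
    """
    mapping = _codon_map(code_id)
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} not divisible by 3")
    out = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon == "---":
            out.append("-")
        elif "-" in codon:
            warnings.warn(
                f"partial-gap codon {codon!r} at codon {i}; translated as X",
                stacklevel=2,
            )
            out.append("X")
        elif codon in mapping:
            aa = mapping[codon]
            if aa == "*" and i < n_codons - 1:
                warnings.warn(
                    f"internal stop codon {codon!r} at codon {i}", stacklevel=2
                )
            out.append(aa)
        else:  # contains N or other ambiguity
            out.append("X")
    return "".join(out)


def translate_alignment(cds: Alignment, code_id: int) -> Alignment:
    """Column-wise translation of a nucleotide alignment to amino acids."""
    if cds.alphabet != "nt":
        raise UsageError("translate_alignment expects a nucleotide alignment")
    return Alignment(
        {t: translate_cds(s, code_id) for t, s in cds.records.items()}, "aa"
    )


# --- concatenation -----------------------------------------------------------

def concat_supermatrix(
    alignments: Sequence[Alignment],
    names: Sequence[str] | None = None,
) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """Concatenate per-gene alignments into a supermatrix.

    The output taxon set is the union of the inputs' taxa; genes missing a
    taxon are filled with gaps. Returns the supermatrix and a mapping of gene
    name -> half-open column range ``(start, end)``.
    """
    if not alignments:
        raise UsageError("concat_supermatrix requires at least one alignment")
    alphabet = alignments[0].alphabet
    if any(a.alphabet != alphabet for a in alignments):
        raise AlphabetError("cannot concatenate alignments with mixed alphabets")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alignments))]
    if len(names) != len(alignments):
        raise UsageError("names and alignments must have equal length")

    taxa: list[str] = []
    seen = set()
    for aln in alignments:
        for t in aln.taxa:
            if t not in seen:
                seen.add(t)
                taxa.append(t)

    parts: dict[str, list[str]] = {t: [] for t in taxa}
    ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, aln in zip(names, alignments):
        gap_fill = "-" * aln.length
        for t in taxa:
            parts[t].append(aln.records.get(t, gap_fill))
        ranges[name] = (offset, offset + aln.length)
        offset += aln.length
    merged = Alignment({t: "".join(chunks) for t, chunks in parts.items()}, alphabet)
    return merged, ranges


# --- gene records and the metadata table -------------------------------------

_DEFAULT_CODE = {"mito": 5, "nuclear": 1}

META_COLUMNS = ["gene_id", "source", "genetic_code", "cds_path", "aa_path", "tree_path"]


@dataclass
class GeneRecord:
    """One gene: amino-acid alignment, optional CDS, provenance and code."""

    gene_id: str
    source: str  # "mito" | "nuclear"
    aa: Alignment
    cds: Alignment | None = None
    genetic_code: int | None = None

    def __post_init__(self) -> None:
        if self.source not in _DEFAULT_CODE:
            raise UsageError(
                f"gene {self.gene_id}: source must be 'mito' or 'nuclear', "
                f"got {self.source!r}"
            )
        if self.genetic_code is None:
            self.genetic_code = _DEFAULT_CODE[self.source]
        if self.genetic_code not in SUPPORTED_CODES:
            raise UnsupportedCodeError(
                f"gene {self.gene_id}: unsupported genetic code {self.genetic_code}"
            )
        if self.aa.alphabet != "aa":
            raise UsageError(f"gene {self.gene_id}: aa alignment must have aa alphabet")
        if self.cds is not None:
            if self.cds.alphabet != "nt":
                raise UsageError(
                    f"gene {self.gene_id}: cds alignment must have nt alphabet"
                )
            if self.cds.length != 3 * self.aa.length:
                raise AlignmentShapeError(
                    f"gene {self.gene_id}: cds length {self.cds.length} != "
                    f"3 x aa length {self.aa.length}"
                )


def load_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the gene metadata TSV (columns: gene_id, source, genetic_code,
    cds_path, aa_path, tree_path)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    return df


def load_genes(
    meta_path: str | Path,
    with_trees: bool = True,
) -> tuple[dict[str, GeneRecord], dict[str, dendropy.Tree]]:
    """Load all gene records (and, optionally, their trees) from a metadata TSV.

    Relative paths in the table are resolved against the table's directory.
    """
    meta_path = Path(meta_path)
    base = meta_path.parent
    df = load_gene_table(meta_path)
    records: dict[str, GeneRecord] = {}
    trees: dict[str, dendropy.Tree] = {}
    for row in df.itertuples(index=False):
        aa = read_fasta(base / row.aa_path, "aa")
        cds = None
        if isinstance(row.cds_path, str) and row.cds_path:
            cds = read_fasta(base / row.cds_path, "nt")
        records[row.gene_id] = GeneRecord(
            gene_id=row.gene_id,
            source=row.source,
            aa=aa,
            cds=cds,
            genetic_code=int(row.genetic_code),
        )
        if with_trees and isinstance(row.tree_path, str) and row.tree_path:
            trees[row.gene_id] = read_newick(base / row.tree_path)
    return records, trees
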
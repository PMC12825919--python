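"""GC-window partitioning of genes and within-group topological discordance.

Genes are assigned to non-overlapping half-open GC windows (e.g. the nuclear
low/medium/high groups [0.38, 0.40), [0.42, 0.44), [0.46, 0.48)); within each
group all pairwise normalized Robinson-Foulds distances among the member
gene trees are collected. A rising within-group median with rising GC is the
signature of GC-coupled discordance. Functional-category proportions per
group are computed from a precomputed gene -> category table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError, UsageError
from .tree_compare import pairwise_nrf_matrix

Window = tuple[float, float]


def _window_label(w: Window) -> str:
    return f"{w[0]:g}-{w[1]:g}"


@dataclass
class GCPartition:
    """Assignment of genes to ordered, non-overlapping GC windows."""

    windows: list[Window]
    labels: list[str]
    assignment: dict[str, str]  # gene_id -> window label
    unassigned: list[str]

    def genes_in(self, label: str) -> list[str]:
        return [g for g, lab in self.assignment.items() if lab == label]

    @property
    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in self.labels}
        for lab in self.assignment.values():
            out[lab] += 1
        return out


def validate_windows(windows: Sequence[Window]) -> list[Window]:
    ws = [(float(lo), float(hi)) for lo, hi in windows]
    for lo, hi in ws:
        if not lo < hi:
            raise ConfigurationError(f"window ({lo}, {hi}) must satisfy lo < hi")
    ordered = sorted(ws)
    for (l1, h1), (l2, h2) in zip(ordered, ordered[1:]):
        if l2 < h1:
            raise ConfigurationError(
                f"windows [{l1},{h1}) and [{l2},{h2}) overlap"
            )
    return ws


def partition_by_gc(
    properties: pd.DataFrame,
    windows: Sequence[Window],
    labels: Sequence[str] | None = None,
    gc_column: str = "gc_content",
) -> GCPartition:
    """Assign each gene to the unique half-open window [lo, hi) containing
    its GC value; genes in no window (or with missing GC) stay unassigned."""
    ws = validate_windows(windows)
    if labels is None:
        labels = [_window_label(w) for w in ws]
    elif len(labels) != len(ws):
        raise ConfigurationError("labels and windows must have equal length")
    if gc_column not in properties.columns:
        raise ConfigurationError(f"column {gc_column!r} not in properties table")
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for row in properties.itertuples():
        gid = row.gene_id
        gc = getattr(row, gc_column)
        if gc is None or (isinstance(gc, float) and np.isnan(gc)):
            unassigned.append(gid)
            continue
        for (lo, hi), lab in zip(ws, labels):
            if lo <= gc < hi:
                assignment[gid] = lab
                break
        else:
            unassigned.append(gid)
    return GCPartition(ws, list(labels), assignment, unassigned)


@dataclass
class GroupDiscordance:
    """Within-group pairwise nRF distribution summary."""

    label: str
    n_genes: int
    values: np.ndarray
    median: float
    iqr_low: float
    iqr_high: float


def within_group_pairwise_nrf(
    partition: GCPartition, trees: Mapping[str, dendropy.Tree]
) -> dict[str, GroupDiscordance]:
    """All C(k, 2) pairwise nRF values among the gene trees of each group.

    Groups with fewer than two trees yield an empty distribution (median NaN)
    rather than an error.
    """
    out: dict[str, GroupDiscordance] = {}
    for label in partition.labels:
        genes = [g for g in partition.genes_in(label) if g in trees]
        if len(genes) < 2:
            out[label] = GroupDiscordance(
                label, len(genes), np.array([]), float("nan"),
                float("nan"), float("nan"),
            )
            continue
        _, flat = pairwise_nrf_matrix({g: trees[g] for g in genes})
        q1, q3 = np.percentile(flat, [25, 75])
        out[label] = GroupDiscordance(
            label, len(genes), flat, float(np.median(flat)), float(q1), float(q3)
        )
    return out


def discordance_summary(groups: Mapping[str, GroupDiscordance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": g.label,
                "n_genes": g.n_genes,
                "n_pairs": len(g.values),
                "median_nrf": g.median,
                "iqr_low": g.iqr_low,
                "iqr_high": g.iqr_high,
            }
            for g in groups.values()
        ]
    )


def category_proportions(
    partition: GCPartition, categories: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-group proportion of genes carrying each category label.

    A gene with several labels increments each of them once, so rows may sum
    to more than 1. Groups with no genes yield NaN rows.
    """
    cat_of: dict[str, set[str]] = {g: set(v) for g, v in categories.items()}
    all_labels = sorted({c for v in cat_of.values() for c in v})
    rows = {}
    for label in partition.labels:
        genes = partition.genes_in(label)
        if not genes:
            rows[label] = {c: float("nan") for c in all_labels}
            continue
        rows[label] = {
            c: sum(1 for g in genes if c in cat_of.get(g, ())) / len(genes)
            for c in all_labels
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=all_labels)


def load_category_table(path) -> dict[str, set[str]]:
    """Read a two-column TSV (gene_id, category) into a multi-label mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "category"}.issubset(df.columns):
        raise ConfigurationError("category table needs columns gene_id, category")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        if not str(row.category).strip():
            raise ConfigurationError(f"empty category label for gene {row.gene_id}")
        out.setdefault(row.gene_id, set()).add(str(row.category))
    return out


def largest_gap_split(values: Sequence[float]) -> list[Window]:
    """Two windows split at the midpoint of the largest gap between sorted
    values (used for the mitochondrial two-group split, where no published
    bounds exist)."""
    vals = sorted(float(v) for v in values)
    if len(vals) < 2:
        raise UsageError("largest_gap_split requires >= 2 values")
    gaps = [(b - a, 0.5 * (a + b)) for a, b in zip(vals, vals[1:])]
    _, cut = max(gaps)
    eps = 1e-9
    return [(vals[0] - eps, cut), (cut, vals[-1] + eps)]
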
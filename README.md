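# gcdiscord

Phylogenetic trees built from mitochondrial genes routinely conflict with
trees built from nuclear genes of the same species — *mito-nuclear
discordance*. `gcdiscord` is a toolkit for asking *which gene property
drives that conflict*. It implements the comparison and resampling machinery
used to dissect discordance in large phylogenomic datasets (many nuclear
single-copy genes plus the 13 mitochondrial protein-coding genes), together
with a synthetic-data generator that plants a known GC–discordance coupling,
so the whole analysis is testable end to end without any external data.

It is aimed at molecular evolution researchers who want to
quantify topological conflict between gene trees, screen per-gene properties
for association with that conflict, and control their pipelines with planted
ground truth.

## What it computes

**Topological discordance** between two trees is the normalized
Robinson–Foulds distance

nRF(T₁, T₂) = |Σ(T₁) △ Σ(T₂)| / (|Σ(T₁)| + |Σ(T₂)|),

where Σ(T) is the set of non-trivial bipartitions of the unrooted tree.
nRF is 0 for identical topologies and 1 when no split is shared; the
denominator equals the usual 2(n−3) for binary trees and stays defined for
polytomies.

**Nine per-gene properties**: alignment length (amino-acid sites), GC
content, amino-acid substitution saturation (slope of uncorrected p-distance
on patristic distance, zero intercept), effective number of amino acids
(mean per-site exp-entropy, 1–20), proportions of constant and of
parsimony-informative sites, median external branch length, mean bootstrap
support, and treeness (internal / total branch length). Codon-position GC
(GC1/GC2/GC3) and amino-acid usage spectra come along for compositional
diagnostics.

**Property-matched resampling**: for a chosen property, each replicate picks
one "mito-like" nuclear gene per mitochondrial gene (within ±5% relative
tolerance, without replacement), concatenates them, builds a tree
(neighbor joining on Poisson-corrected amino-acid distances, with column
bootstrap for supports), and measures its nRF to the mitochondrial
concatenation tree; a background arm draws nuclear genes uniformly. A
property that matters pulls the matched arm below the background.

**GC partitioning**: genes binned into half-open GC windows (e.g.
[0.38, 0.40), [0.42, 0.44), [0.46, 0.48)); within each group all pairwise
gene-tree nRF values are collected. Rising within-group medians with rising
GC is the signature of GC-coupled discordance.

**Synthetic data**: a Yule species tree (unit mean depth), per-gene trees
perturbed by NNI moves whose number grows with the gene's GC (`kappa`
controls the coupling; high-GC genes additionally share a common conflicting
trajectory), amino-acid sequences evolved under a composition-stationary
model tied to GC class, and coding sequences produced by synonymous
back-translation calibrated to hit each gene's GC target — under the
standard nuclear code or the invertebrate mitochondrial code.

## Worked example

```python
import numpy as np
import pandas as pd
from gcdiscord import (SyntheticConfig, generate_dataset,
                       MatchingConfig, run_matching_experiment)
from gcdiscord.gene_properties import gc_content
from gcdiscord.workflow import concat_source_tree

cfg = SyntheticConfig(seed=0)           # 24 taxa, 13 mito + 60 nuclear genes
ds = generate_dataset(cfg)

props = pd.DataFrame(
    {"gene_id": gid, "source": r.source, "gc_content": gc_content(r.cds)}
    for gid, r in ds.records.items()
)
print(props.groupby("source")["gc_content"].median().round(3))

reference = concat_source_tree(ds.records, "mito")   # mitochondrial tree
result = run_matching_experiment(
    ds.records, props, reference,
    MatchingConfig("gc_content", tolerance=0.05, replicates=20, seed=7),
)
print("matched median nRF:   ", round(np.median(result.matched_nrf), 3))
print("background median nRF:", round(np.median(result.background_nrf), 3))
```

prints

```
source
mito       0.250
nuclear    0.435
Name: gc_content, dtype: float64
matched median nRF:    0.048
background median nRF: 0.143
```

The mitochondrial genes are AT-rich (median GC 0.25) while nuclear genes sit
near 0.43. Selecting the 13 nuclear genes closest to mitochondrial GC
content yields trees far closer to the mitochondrial tree (median nRF 0.048)
than random 13-gene sets (0.143): in this dataset GC content carries the
discordance signal. Repeating with `MatchingConfig("alignment_length", ...)`
shows no such reduction.

## Command line

```bash
gcdiscord simulate --seed 0 --outdir data/              # synthetic dataset
gcdiscord trees    --genes data/meta.tsv --boot 100 --seed 1 --outdir trees/
gcdiscord props    --genes data/meta.tsv --out properties.tsv
gcdiscord compare  --tree1 trees/concat_mito.nwk --tree2 trees/concat_nuclear.nwk
gcdiscord match    --genes data/meta.tsv --props properties.tsv \
                   --ref trees/concat_mito.nwk --property gc_content \
                   --tol 0.05 --reps 20 --seed 7 --out match_gc.tsv
gcdiscord partition --props properties.tsv --trees trees/ \
                   --windows 0.38:0.40,0.42:0.44,0.46:0.48 --out partition
gcdiscord run      --config pipeline.yaml               # full pipeline + manifest
```

## Layout

- `src/gcdiscord/seqio.py` — FASTA/Newick/metadata I/O, genetic codes 1 and 5, supermatrix concatenation
- `src/gcdiscord/gene_properties.py` — the nine metrics, codon-position GC, amino-acid usage
- `src/gcdiscord/tree_compare.py` — bipartitions, RF/nRF, pairwise matrices
- `src/gcdiscord/tree_build.py` — distances, deterministic NJ, column bootstrap, external-ML adapter
- `src/gcdiscord/matching.py` — property-matched resampling
- `src/gcdiscord/gc_partition.py` — GC windows, within-group discordance, category proportions
- `src/gcdiscord/simulate.py` — the synthetic-data generator
- `src/gcdiscord/workflow.py`, `src/gcdiscord/cli.py` — orchestration and the `gcdiscord` command

See `docs/methods.md` for the models, parameter choices and limitations.
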
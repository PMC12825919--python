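# Methods

This note records the models behind `gcdiscord`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that matter when comparing results.

## Tree distance

Discordance is measured exclusively as normalized Robinson–Foulds distance.
Bipartitions are taken from the unrooted tree, one per internal edge,
excluding pendant splits; each split is canonicalized as the block
containing the lexicographically smallest taxon, so a rooted input with a
bifurcating root contributes no duplicate split. The normalization divides
the symmetric-difference count by the *total* number of non-trivial splits
in the two trees. For two binary trees on n shared taxa this is the familiar
RF / 2(n−3); for polytomous trees it remains well defined, and two star
trees are at distance 0 by convention. Trees with different tip sets are
pruned to their shared taxa first (at least four required).

## Gene properties

Composition metrics pool residues over all sequences of a gene. Gaps and
ambiguity codes (N for nucleotides; X and stop for amino acids) are excluded
from both numerator and denominator — GC content is the composition of
observed bases, not of alignment cells. Codon-position GC applies the same
rule per frame offset, and the three positions pool back exactly to overall
GC when weighted by per-position countable-base counts (a tested
invariant).

Constant-site counting treats a column as constant when its unambiguous
non-gap residues are all identical; all-gap columns count as constant,
matching the convention of the ML-software log summaries such proportions
are usually read from. Parsimony-informative columns need at least two
states each carried by at least two sequences; gaps and X are not states.

The effective number of amino acids is exp of the natural-log Shannon
entropy of each column's residue frequencies, averaged over columns with at
least one countable residue. The per-site-then-mean aggregation is a
deliberate choice (the per-gene aggregation of this family of diversity
statistics is not standardized); it preserves the defining limits 1.0
(single residue everywhere) and 20.0 (every column uniform over all 20).

Saturation is the slope of the zero-intercept least-squares fit of pairwise
uncorrected amino-acid p-distance on pairwise patristic distance
(Σxy / Σx², clamped to [0, 1]). The orientation and the forced zero
intercept make the no-saturation limit exactly 1: if observed distances
track tree distances linearly, nothing has been erased by multiple hits.
Sites with a gap in either sequence of a pair are excluded pairwise.

Treeness is computed on the unrooted form (a bifurcating root is collapsed
first) so an arbitrary root edge cannot inflate the internal-branch sum.
Mean bootstrap averages only internal nodes that carry a support value; the
root is excluded.

## Tree engine

The internal engine is neighbor joining on amino-acid distances, either
uncorrected p-distances or the Poisson correction −ln(1 − p) with p capped
at 0.95 to keep distances finite (the cap is configurable). NJ is fully
deterministic: Q-criterion ties (within a 1e−10 relative tolerance) are
broken by the lexicographically smallest pair of cluster keys, a cluster's
key being the smallest taxon label it contains, so input order never
changes the topology. Negative branch-length estimates are clamped to zero.
Supports come from nonparametric bootstrap over alignment columns (default
100 replicates), annotated as the percentage of replicate trees containing
each split of the full-data tree.

The analysis layer is engine-agnostic. An adapter can shell out to an
external maximum-likelihood command (template with `{aln}`/`{out}`
placeholders, reading `{out}.treefile`); it is feature-flagged and not used
by any default path. Likelihood computation, model selection and
site-heterogeneous mixture models are intentionally out of scope: the
package's contribution is the comparison and matching machinery around the
tree engine, not the engine itself.

## Property matching

For a property value v of a mitochondrial gene, a nuclear gene with value w
is a candidate when |w − v| / |v| < 0.05. The relative-tolerance rule is
applied to all nine properties uniformly. Each replicate selects one
candidate per mitochondrial gene, without replacement, drawing uniformly at
random among unused in-tolerance candidates; mitochondrial genes are
processed scarcest-first (fewest candidates first) to minimize dead ends.
When no unused candidate remains, the unused nuclear gene with the smallest
relative difference is taken and the event is logged as a fallback — the
experiment size stays fixed and the audit trail records how often the
tolerance was violated. With mitochondrial GC near 0.25 and nuclear GC near
0.43, GC matching runs entirely on fallbacks and deterministically selects
the lowest-GC nuclear genes; this mirrors the real situation, where the two
genomes' GC distributions barely overlap. The background arm draws
uniformly random distinct nuclear gene sets of the same size. Every
replicate's random stream is derived from (experiment seed, arm, replicate
index), so any replicate is independently reproducible.

The summary table reports matched and background medians and their
difference; a rank-sum p-value column is included but labeled exploratory —
the protocol is a designed contrast, not a formal test.

## Synthetic data

The generator produces datasets with the causal structure the analysis is
meant to detect: gene-tree discordance that rises with GC content, on top
of realistic compositional differences between an AT-rich mitochondrial
gene set (13 genes, invertebrate mitochondrial code) and a nuclear gene
pool (standard code, GC ≈ 0.36–0.50).

**Species tree.** Pure-birth (Yule) with exponential waiting times,
normalized to mean root-to-tip depth exactly 1.0. Internal branches are
floored at 2% of tree depth before normalization (`min_internal_branch`):
Yule trees otherwise contain near-zero recent internal edges that no
desk-scale amount of sequence can resolve, and such edges turn every
concatenation comparison into noise. The floor models radiations that are
rapid but resolvable.

**Gene trees.** A gene with GC value g (rank-scaled to θ ∈ [0, 1] over the
configured GC range) receives m = round(κ·θ) nearest-neighbor-interchange
moves away from the species tree; κ (default 6) is the single coupling
knob, and κ = 0 is the null model in which every gene tree equals the
species tree. Two components make up the perturbation:

- *gene-specific*: all m moves are independent random NNIs — genes of equal
  GC still disagree with each other, which is what the within-GC-window
  pairwise comparisons measure;
- *shared*: genes with m > 2 additionally start from stage 3·(m − 2) of a
  dataset-wide random NNI trajectory. High-GC genes are thereby pulled
  toward a common conflicting topology. Without a shared component,
  independent per-gene conflicts average out under 13-gene concatenation
  and no property-matching contrast can exist at all; biologically, the
  shared component stands in for mechanisms like GC-biased gene conversion
  that push compositionally similar genes toward similar (wrong)
  topologies. Mitochondrial gene trees get one gene-specific move each.

**Sequences.** Amino acids evolve site-independently under an
equal-exchange, composition-stationary (F81-style, 20-state) model whose
stationary frequencies interpolate with θ between a low-GC-codon set
(F, I, K, L, M, N, Y up-weighted at θ = 0) and a high-GC set
(A, G, P, R, W at θ = 1), bias weight 3. Substitution probability along a
branch of length b is 1 − exp(−μb) with μ scaled so `rate` (default 0.5) is
the expected substitutions per site per unit depth. The rate was chosen so
that multi-gene concatenations resolve the species tree while single genes
retain realistic estimation noise; it corresponds to moderately saturated
deep-phylogeny alignments.

**Coding sequences.** Each residue is replaced by a synonymous codon of the
gene's genetic code with probability ∝ exp(β·(1 − |GC3(codon) − g₃|)),
β = 2. The per-gene preference g₃ is found by bisection so the expected
overall GC of the back-translated alignment equals the gene's GC target;
translating the result reproduces the amino acids exactly, and no stop
codons are ever emitted. Amino-acid composition (via θ) and nucleotide GC
are thereby linked without a codon substitution model, reproducing the
two-level signature of compositional bias (AT-ending codon preference and
AT-rich amino-acid usage in low-GC genes).

**Lengths.** Gene lengths are drawn uniformly from 100–350 codons for both
sources, and the nuclear GC↔length pairing uses a low-discrepancy stride
(every length window sees an even spread of GC ranks). Both choices serve
one purpose: alignment length is the *designed-null* property of the
matching experiment, and in a 60-gene pool either a chance GC–length
correlation or a systematic length difference between sources (matched sets
would concatenate fewer sites than background sets) makes the null property
spuriously informative. The marginal fact that real mitochondrial genes are
shorter than nuclear genes is intentionally not reproduced.

**Determinism.** All randomness derives from one seed via keyed
`SeedSequence` spawning; identical configurations produce byte-identical
output files.

## What passing tests show — and what they do not

The synthetic data carries the planted causal structure and nothing else:
no indels, no rate heterogeneity across sites or lineages, no alignment or
trimming error, no coalescent or introgression process, no codon-level
substitution model. Passing the end-to-end checks shows that the pipeline
*detects a GC–discordance coupling when it exists and reports none when it
does not* — it does not certify any claim about real organisms. Because the
generator ties amino-acid composition to GC by construction,
composition-derived properties (e.g. the effective number of amino acids)
are partially informative for discordance in synthetic data; only alignment
length is constructed to be exactly null.

The headline end-to-end checks run on the canonical dataset (24 taxa,
13 + 60 genes, κ = 6, seed 0) with 20 experiment seeds. The strict
count-based bounds (GC matching lowers the median in ≥ 18/20 seeds, length
matching in ≤ 4/20) are stable for the GC arm across every dataset seed
examined; the length-null count is usually within its bound but, over
arbitrary dataset seeds, occasionally exceeds it because a 60-gene pool
cannot fully prevent accidental confounding between the matching windows
and the coupling — the qualitative contrast (GC strong, length null-ish)
held in every dataset examined.

## Numerical conventions and degenerate inputs

- GC windows are half-open [lo, hi); a gene at exactly the upper bound is
  unassigned unless another window opens there.
- The two-group mitochondrial GC split, where needed, is data-driven: the
  midpoint of the largest gap between sorted GC values.
- Groups with fewer than two trees yield empty distributions (median NaN),
  not errors; pairs of star trees compare at nRF 0.
- Zero-valued reference properties make relative tolerance undefined and
  raise immediately, as do alignments with no countable residues and trees
  with zero total branch length.
- Bootstrap replicates that lose all comparable columns for some taxon pair
  are skipped (supports stay percentages of the requested replicate count).
- p-distance caps (0.95 before Poisson correction) and branch-length clamps
  (negative NJ estimates to zero) are the only silent numerical guards.
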
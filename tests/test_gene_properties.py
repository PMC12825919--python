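"""The nine per-gene metrics: closed forms, brute-force oracles, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcdiscord.errors import (
    DegenerateTreeError,
    MissingSupportError,
    UndefinedCompositionError,
    UsageError,
)
from gcdiscord.gene_properties import (
    aa_usage,
    compute_all_properties,
    effective_number_of_aa,
    gc_by_codon_position,
    gc_content,
    mean_bootstrap,
    median_external_branch_length,
    prop_constant_sites,
    prop_parsimony_informative,
    properties_table,
    saturation,
    treeness,
)
from gcdiscord.seqio import AA20, Alignment, read_newick
from gcdiscord.tree_build import bootstrap_support, patristic_distance_matrix


def aa_aln(*seqs: str) -> Alignment:
    return Alignment({f"t{i}": s for i, s in enumerate(seqs)}, "aa")


def nt_aln(*seqs: str) -> Alignment:
    return Alignment({f"t{i}": s for i, s in enumerate(seqs)}, "nt")


class TestGCContent:
    @pytest.mark.parametrize(
        "seqs,expected",
        [(("ATGC",), 0.5), (("GGCC",), 1.0), (("A-GC", "ATGC"), 4 / 7)],
    )
    def test_pooled_gc_excluding_gaps(self, seqs, expected):
        assert gc_content(nt_aln(*seqs)) == pytest.approx(expected)

    def test_all_ambiguous_undefined(self):
        with pytest.raises(UndefinedCompositionError):
            gc_content(nt_aln("NN--"))

    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGGCA", (0.5, 0.5, 0.5)), ("GGGGGG", (1, 1, 1)), ("ATAATA", (0, 0, 0))],
    )
    def test_codon_position_gc(self, seq, expected):
        res = gc_by_codon_position(nt_aln(seq))
        assert (res.gc1, res.gc2, res.gc3) == pytest.approx(expected)

    def test_position_gc_pools_back_to_overall(self, small_dataset):
        for rec in list(small_dataset.records.values())[:5]:
            res = gc_by_codon_position(rec.cds)
            mat = rec.cds.matrix()
            weights = [
                np.isin(mat[:, off::3], list("ACGT")).sum() for off in range(3)
            ]
            pooled = np.average([res.gc1, res.gc2, res.gc3], weights=weights)
            assert pooled == pytest.approx(gc_content(rec.cds), abs=1e-12)


class TestAAUsage:
    def test_single_residue(self):
        usage = aa_usage(aa_aln("LLLL"))
        assert usage["L"] == 1.0 and usage.sum() == pytest.approx(1.0)

    def test_even_split_excludes_gaps(self):
        usage = aa_usage(aa_aln("LA-X", "LA--"))
        assert usage["L"] == usage["A"] == 0.5

    def test_low_gc_gene_favors_at_rich_amino_acids(self, small_dataset):
        recs = sorted(
            (r for r in small_dataset.records.values() if r.source == "nuclear"),
            key=lambda r: gc_content(r.cds),
        )
        low, high = aa_usage(recs[0].aa), aa_usage(recs[-1].aa)
        at_set = list("FIKLMNY")
        assert low[at_set].sum() > high[at_set].sum()


class TestSiteClasses:
    def test_constant_and_informative_examples(self):
        aln = aa_aln("AA", "AA", "AT", "AT")
        assert prop_constant_sites(aln) == 0.5
        assert prop_parsimony_informative(aln) == 0.5
        singleton = aa_aln("A", "T", "C", "G")
        assert prop_parsimony_informative(singleton) == 0.0

    def test_all_gap_column_counts_constant(self):
        assert prop_constant_sites(aa_aln("A-", "A-", "A-")) == 1.0
        assert prop_constant_sites(aa_aln("A-", "--", "-A")) == 1.0

    def test_matches_bruteforce_column_scan(self):
        rng = np.random.default_rng(42)
        chars = list(AA20 + "-X")
        mat = rng.choice(chars, size=(6, 100), p=[0.04] * 20 + [0.1, 0.1])
        aln = Alignment(
            {f"t{i}": "".join(row) for i, row in enumerate(mat)}, "aa"
        )
        const = inf = 0
        for col in mat.T:
            states = [c for c in col if c in AA20]
            const += len(set(states)) <= 1
            counts = {s: states.count(s) for s in set(states)}
            inf += sum(v >= 2 for v in counts.values()) >= 2
        assert prop_constant_sites(aln) == pytest.approx(const / 100)
        assert prop_parsimony_informative(aln) == pytest.approx(inf / 100)

    def test_preconditions(self):
        with pytest.raises(UsageError):
            prop_constant_sites(aa_aln("AA"))
        with pytest.raises(UsageError):
            prop_parsimony_informative(aa_aln("AA", "AA", "AA"))


class TestEffectiveNumberOfAA:
    def test_limits_one_and_twenty(self):
        assert effective_number_of_aa(aa_aln("AAA", "AAA")) == pytest.approx(1.0)
        uniform = Alignment({f"t{i}": AA20 for i in range(1)}, "aa")
        # one residue per column is not uniform; build columns holding all 20
        cols = Alignment({f"t{i}": AA20[i] * 5 for i in range(20)}, "aa")
        assert effective_number_of_aa(cols) == pytest.approx(20.0)
        del uniform

    def test_fifty_fifty_column_is_two(self):
        assert effective_number_of_aa(aa_aln("A", "A", "T", "T")) == pytest.approx(2.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_invariant_under_row_and_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.choice(list(AA20 + "-"), size=(5, 30))
        aln = Alignment({f"t{i}": "".join(r) for i, r in enumerate(mat)}, "aa")
        rows = rng.permutation(5)
        cols = rng.permutation(30)
        perm = Alignment(
            {f"t{i}": "".join(mat[r][cols]) for i, r in enumerate(rows)}, "aa"
        )
        assert effective_number_of_aa(aln) == pytest.approx(
            effective_number_of_aa(perm), abs=1e-12
        )


class TestSaturation:
    def test_identity_and_half_slope(self):
        tree = read_newick(None, data="((A:1,B:1):1,(C:1,D:1):1);")
        pat = patristic_distance_matrix(tree)
        # alignment whose p-distances exactly track patristic: impossible in
        # general, so check against the closed-form oracle instead
        rng = np.random.default_rng(0)
        aln = Alignment(
            {t: "".join(rng.choice(list(AA20), size=50)) for t in pat.taxa}, "aa"
        )
        from gcdiscord.tree_build import aa_distance_matrix

        p = aa_distance_matrix(aln, model="p")
        iu = np.triu_indices(4, k=1)
        x, y = pat.values[iu], p.values[iu]
        expected = min(max(float(x @ y / (x @ x)), 0.0), 1.0)
        assert saturation(aln, tree) == pytest.approx(expected, abs=1e-10)

    def test_zero_patristic_degenerate(self):
        tree = read_newick(None, data="((A:0,B:0):0,(C:0,D:0):0);")
        aln = aa_aln("AAAA")
        aln = Alignment({t: "AAAA" for t in "ABCD"}, "aa")
        with pytest.raises(DegenerateTreeError):
            saturation(aln, tree)


class TestTreeMetrics:
    def test_treeness_definition_and_star_limit(self):
        tree = read_newick(None, data="((A:2,B:2):1,(C:2,D:2):1);")
        assert treeness(tree) == pytest.approx(2 / 10)
        star = read_newick(None, data="(A:1,B:1,C:1,D:1);")
        assert treeness(star) == 0.0

    def test_treeness_complement_identity(self, small_dataset):
        for tree in list(small_dataset.gene_trees.values())[:5]:
            t = treeness(tree)
            ext = sum(lf.edge.length or 0 for lf in tree.leaf_node_iter())
            total = sum(
                e.length or 0
                for e in tree.preorder_edge_iter()
                if e.tail_node is not None
            )
            assert t + ext / total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("((A:1,B:2):1,(C:3,D:9):1);", 2.5),
            ("((A:1,B:2):1,(C:3,D:3,E:9):1);", 3.0),
        ],
    )
    def test_median_external_branch(self, newick, expected):
        assert median_external_branch_length(
            read_newick(None, data=newick)
        ) == pytest.approx(expected)

    def test_mean_bootstrap(self):
        tree = read_newick(None, data="((A,B)90,((C,D)100,E));")
        assert mean_bootstrap(tree) == pytest.approx(95.0)
        bare = read_newick(None, data="((A,B),(C,D));")
        with pytest.raises(MissingSupportError):
            mean_bootstrap(bare)


class TestAggregation:
    def test_all_metrics_within_bounds(self, small_dataset):
        records = small_dataset.records
        trees = {
            gid: bootstrap_support(rec.aa, replicates=10, seed=i)
            for i, (gid, rec) in enumerate(list(records.items())[:8])
        }
        table = properties_table(
            {g: records[g] for g in trees}, trees
        )
        assert len(table) == 8
        assert table["gc_content"].between(0, 1).all()
        assert table["saturation"].between(0, 1).all()
        assert table["enaa"].between(1, 20).all()
        assert table["prop_constant"].between(0, 1).all()
        assert table["prop_informative"].between(0, 1).all()
        assert (
            table["prop_constant"] + table["prop_informative"] <= 1 + 1e-12
        ).all()
        assert table["mean_bootstrap"].between(0, 100).all()
        assert table["treeness"].between(0, 1).all()

    def test_missing_cds_flags_gc_unavailable(self, small_dataset):
        gid, rec = next(iter(small_dataset.records.items()))
        from gcdiscord.seqio import GeneRecord

        no_cds = GeneRecord(gid, rec.source, rec.aa, None, rec.genetic_code)
        tree = bootstrap_support(rec.aa, replicates=5, seed=0)
        props = compute_all_properties(no_cds, tree)
        assert props.gc_content is None and props.gc1 is None
        assert 1 <= props.enaa <= 20

    def test_errors_tagged_with_gene_id(self, small_dataset):
        gid, rec = next(iter(small_dataset.records.items()))
        star = read_newick(
            None,
            data="(" + ",".join(f"{t}:0" for t in rec.aa.taxa) + ");",
        )
        with pytest.raises(Exception, match=gid):
            compute_all_properties(rec, star)
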
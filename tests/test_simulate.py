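"""The synthetic-data generator: species trees, NNI perturbation, sequence
evolution, back-translation, and the assembled dataset's causal structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gcdiscord.errors import ConfigurationError, EncodingError, UsageError
from gcdiscord.gene_properties import gc_content
from gcdiscord.seqio import AA20, newick_string, translate_alignment
from gcdiscord.simulate import (
    HIGH_GC_AA,
    LOW_GC_AA,
    SyntheticConfig,
    back_translate,
    calibrate_gc3_target,
    evolve_aa,
    generate_dataset,
    perturb_topology,
    simulate_species_tree,
    stationary_frequencies,
    write_dataset,
)
from gcdiscord.tree_compare import nrf_distance
from gcdiscord.gene_properties import gc_by_codon_position


class TestSpeciesTree:
    def test_shape_and_tip_count(self):
        tree = simulate_species_tree(8, np.random.default_rng(0))
        leaves = list(tree.leaf_node_iter())
        internals = [n for n in tree.preorder_internal_node_iter()]
        assert len(leaves) == 8
        assert len(internals) == 7  # rooted binary: n-1 internal nodes

    def test_same_seed_identical_newick(self):
        a = simulate_species_tree(12, np.random.default_rng(5))
        b = simulate_species_tree(12, np.random.default_rng(5))
        assert newick_string(a) == newick_string(b)

    def test_mean_root_to_tip_normalized(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tree = simulate_species_tree(16, rng, min_internal_branch=0.02)
            depths = []
            for leaf in tree.leaf_node_iter():
                d, nd = 0.0, leaf
                while nd.parent_node is not None:
                    d += nd.edge.length
                    nd = nd.parent_node
                depths.append(d)
            assert np.mean(depths) == pytest.approx(1.0, abs=1e-6)

    def test_internal_branch_floor_applied(self):
        tree = simulate_species_tree(
            24, np.random.default_rng(3), min_internal_branch=0.02
        )
        internal = [
            nd.edge.length
            for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
        ]
        # floor is 2% of depth before normalization; normalization rescales
        # by the (>=1) mean depth, so allow that shrinkage
        assert min(internal) >= 0.02 / 1.5


class TestPerturbation:
    def test_zero_moves_is_identity(self):
        tree = simulate_species_tree(10, np.random.default_rng(2))
        assert nrf_distance(tree, perturb_topology(tree, 0, np.random.default_rng(0))) == 0.0

    def test_single_move_changes_topology(self):
        tree = simulate_species_tree(8, np.random.default_rng(4))
        for s in range(10):
            moved = perturb_topology(tree, 1, np.random.default_rng(s))
            assert nrf_distance(tree, moved) > 0.0

    def test_does_not_mutate_input(self):
        tree = simulate_species_tree(8, np.random.default_rng(4))
        before = newick_string(tree)
        perturb_topology(tree, 3, np.random.default_rng(0))
        assert newick_string(tree) == before

    def test_expected_discordance_monotone_in_moves(self):
        rng = np.random.default_rng(6)
        tree = simulate_species_tree(12, np.random.default_rng(1))
        mean_dist = []
        for m in range(9):
            draws = [
                nrf_distance(tree, perturb_topology(tree, m, rng))
                for _ in range(25)
            ]
            mean_dist.append(np.mean(draws))
        rho = spearmanr(range(9), mean_dist).statistic
        assert rho > 0.9


class TestEvolveAA:
    def test_zero_rate_clones_root(self):
        tree = simulate_species_tree(6, np.random.default_rng(0))
        aln = evolve_aa(tree, 40, theta=0.5, rate=0.0, rng=np.random.default_rng(1))
        seqs = set(aln.records.values())
        assert len(seqs) == 1

    def test_theta_controls_composition(self):
        tree = simulate_species_tree(6, np.random.default_rng(0))
        low = evolve_aa(tree, 2000, 0.0, 0.5, np.random.default_rng(2))
        high = evolve_aa(tree, 2000, 1.0, 0.5, np.random.default_rng(2))

        def frac(aln, residues):
            total = sum(s.count(r) for s in aln.records.values() for r in residues)
            return total / sum(len(s) for s in aln.records.values())

        assert frac(low, LOW_GC_AA) > frac(high, LOW_GC_AA)
        assert frac(high, HIGH_GC_AA) > frac(low, HIGH_GC_AA)

    def test_long_branch_p_distance_approaches_stationary_limit(self):
        # two taxa at enormous distance: p -> 1 - sum(pi^2)
        from gcdiscord.seqio import read_newick
        from gcdiscord.tree_build import aa_distance_matrix

        tree = read_newick(None, data="((A:200,B:200):1,(C:200,D:200):1);")
        aln = evolve_aa(tree, 20000, 0.3, 1.0, np.random.default_rng(3))
        pi = stationary_frequencies(0.3)
        expected = 1.0 - float(pi @ pi)
        p = aa_distance_matrix(aln, "p").values[0, 1]
        assert p == pytest.approx(expected, abs=0.02)


class TestBackTranslate:
    @pytest.mark.parametrize("code", [1, 5])
    def test_roundtrip_exact(self, code):
        rng = np.random.default_rng(code)
        tree = simulate_species_tree(5, np.random.default_rng(0))
        aln = evolve_aa(tree, 120, 0.4, 0.5, rng)
        cds = back_translate(aln, code, beta=2.0, gc3_target=0.4, rng=rng)
        assert translate_alignment(cds, code).records == aln.records

    def test_strong_low_gc3_bias(self):
        rng = np.random.default_rng(9)
        tree = simulate_species_tree(5, np.random.default_rng(0))
        aln = evolve_aa(tree, 800, 0.5, 0.5, rng)
        cds = back_translate(aln, 1, beta=12.0, gc3_target=0.0, rng=rng)
        res = gc_by_codon_position(cds)
        # GC3 floors at the Met+Trp frequency (their only codons end in G)
        floor = sum(
            s.count("M") + s.count("W") for s in aln.records.values()
        ) / sum(len(s) for s in aln.records.values())
        assert res.gc3 == pytest.approx(floor, abs=0.01)
        assert res.gc3 < res.gc1

    def test_beta_zero_matches_uniform_synonymous_expectation(self):
        rng = np.random.default_rng(10)
        tree = simulate_species_tree(5, np.random.default_rng(0))
        aln = evolve_aa(tree, 3000, 0.5, 0.3, rng)
        cds = back_translate(aln, 1, beta=0.0, gc3_target=0.5, rng=rng)
        from gcdiscord.simulate import expected_gc

        counts = {r: sum(s.count(r) for s in aln.records.values()) for r in AA20}
        expected = expected_gc(counts, 1, 0.0, 0.5)
        assert gc_content(cds) == pytest.approx(expected, abs=0.01)

    def test_residue_without_codon_rejected(self):
        from gcdiscord.seqio import Alignment

        aln = Alignment({"t": "MX"}, "aa")
        with pytest.raises(EncodingError):
            back_translate(aln, 1, 2.0, 0.5, np.random.default_rng(0))

    def test_calibration_hits_reachable_targets(self):
        from gcdiscord.simulate import expected_gc

        counts = {r: 50 for r in AA20}
        lo = expected_gc(counts, 1, 2.0, 0.0)
        hi = expected_gc(counts, 1, 2.0, 1.0)
        for target in np.linspace(lo + 0.01, hi - 0.01, 4):
            g3 = calibrate_gc3_target(counts, 1, beta=2.0, target_gc=target)
            assert expected_gc(counts, 1, 2.0, g3) == pytest.approx(target, abs=1e-4)
        # unreachable targets clamp to the boundary
        assert calibrate_gc3_target(counts, 1, 2.0, lo - 0.1) == 0.0
        assert calibrate_gc3_target(counts, 1, 2.0, hi + 0.1) == 1.0


class TestGenerateDataset:
    def test_shape_contract(self, small_dataset):
        ds = small_dataset
        assert len(ds.records) == 13 + 16
        assert set(ds.records) == set(ds.gene_trees)
        for rec in ds.records.values():
            assert rec.cds.length == 3 * rec.aa.length
            code = 5 if rec.source == "mito" else 1
            assert rec.genetic_code == code
            assert translate_alignment(rec.cds, code).records == rec.aa.records

    def test_mito_gc_below_nuclear_gc(self, small_dataset):
        mito = [gc_content(r.cds) for r in small_dataset.records.values()
                if r.source == "mito"]
        nuc = [gc_content(r.cds) for r in small_dataset.records.values()
               if r.source == "nuclear"]
        assert max(mito) < min(nuc)

    def test_gc_couples_to_discordance(self, study_dataset):
        ds = study_dataset
        gcs, dists = [], []
        for gid, rec in ds.records.items():
            if rec.source != "nuclear":
                continue
            gcs.append(gc_content(rec.cds))
            dists.append(nrf_distance(ds.gene_trees[gid], ds.reference))
        assert spearmanr(gcs, dists).statistic > 0.5

    def test_kappa_zero_removes_coupling(self):
        ds = generate_dataset(
            SyntheticConfig(n_taxa=12, n_nuclear_genes=20, kappa=0.0, seed=3)
        )
        dists = [
            nrf_distance(ds.gene_trees[gid], ds.reference)
            for gid, rec in ds.records.items()
            if rec.source == "nuclear"
        ]
        assert set(dists) == {0.0}

    def test_full_determinism_byte_identical_files(self, tmp_path):
        cfg = SyntheticConfig(n_taxa=10, n_nuclear_genes=6, seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(cfg), d1)
        write_dataset(generate_dataset(cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_roundtrip_through_metadata_table(self, tmp_path):
        from gcdiscord.seqio import load_genes

        cfg = SyntheticConfig(n_taxa=10, n_nuclear_genes=6, seed=2)
        ds = generate_dataset(cfg)
        meta = write_dataset(ds, tmp_path)
        records, trees = load_genes(meta)
        assert set(records) == set(ds.records)
        gid = "nuc0001"
        assert records[gid].aa.records == ds.records[gid].aa.records
        assert nrf_distance(trees[gid], ds.gene_trees[gid]) == 0.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(SyntheticConfig(n_taxa=4))
        with pytest.raises(ConfigurationError):
            generate_dataset(SyntheticConfig(kappa=-1))
        with pytest.raises(ConfigurationError):
            generate_dataset(SyntheticConfig(nuclear_gc_clip=(0.5, 0.4)))
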
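import math

import numpy as np
import pytest

from motudelim.alignment_stats import pairwise_differences
from motudelim.simdata import (
    SimConfig,
    _node_heights,
    generate_dataset,
    preset,
    simulate_gene_tree,
    simulate_sequences,
    simulate_species_tree,
)
from motudelim.treeio import PhyloTree, get_support


class TestSpeciesTree:
    def test_single_species(self):
        t = simulate_species_tree(1, 5.0, seed=0)
        assert len(t.tips()) == 1

    def test_determinism(self):
        a = simulate_species_tree(6, 5.0, seed=42)
        b = simulate_species_tree(6, 5.0, seed=42)
        assert a.to_string() == b.to_string()
        c = simulate_species_tree(6, 5.0, seed=43)
        assert c.to_string() != a.to_string()

    def test_root_height_matches_yule_expectation(self):
        # E[height] = sum_{i=2..k} 1/(i*lambda); also decreasing in lambda
        k = 5
        means = {}
        for lam in (2.0, 8.0):
            rng = np.random.default_rng(1)
            hs = []
            for _ in range(600):
                tree = simulate_species_tree(k, lam, rng=rng).tree
                hs.append(_node_heights(tree)[tree.seed_node])
            means[lam] = np.mean(hs)
            expected = sum(1.0 / (lam * i) for i in range(2, k + 1))
            assert means[lam] == pytest.approx(expected, rel=0.15)
        assert means[8.0] < means[2.0]


class TestGeneTree:
    def test_pairwise_tmrca_expectation(self):
        sp = simulate_species_tree(1, 5.0, seed=3)
        rng = np.random.default_rng(3)
        ne = 0.01
        ts = []
        for _ in range(4000):
            gt = simulate_gene_tree(sp, ne, {"sp1": 2}, rng=rng)
            ts.append(_node_heights(gt.tree)[gt.tree.seed_node])
        assert np.mean(ts) == pytest.approx(ne, rel=0.05)

    def test_deep_divergence_gives_reciprocal_monophyly(self):
        rng = np.random.default_rng(8)
        mono = 0
        reps = 60
        for _ in range(reps):
            sp = simulate_species_tree(2, 5.0, rng=rng)
            # force a divergence far beyond Ne
            for nd in sp.tree.preorder_node_iter():
                if nd.edge.length is not None:
                    nd.edge.length = 0.5
            gt = simulate_gene_tree(sp, 0.005, {"sp1": 5, "sp2": 5}, rng=rng)
            grp = {t for t in gt.tips() if t.startswith("sp1")}
            node = gt.mrca(grp)
            mono += PhyloTree.clade_tips(node) == frozenset(grp)
        assert mono == reps

    def test_determinism(self):
        sp = simulate_species_tree(3, 5.0, seed=5)
        a = simulate_gene_tree(sp, 0.001, (4, 4, 4), seed=7)
        b = simulate_gene_tree(sp, 0.001, (4, 4, 4), seed=7)
        assert a.to_string() == b.to_string()

    def test_matches_msprime_single_population(self):
        msprime = pytest.importorskip("msprime")
        n, ne = 8, 0.004
        rng = np.random.default_rng(10)
        sp = simulate_species_tree(1, 5.0, rng=rng)
        ours = []
        for _ in range(1500):
            tree = simulate_gene_tree(sp, ne, {"sp1": n}, rng=rng).tree
            ours.append(_node_heights(tree)[tree.seed_node])
        theirs = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=ne,
                num_replicates=1500, random_seed=11,
            )
        ]
        # same expected TMRCA: 2*Ne*(1 - 1/n)
        expected = 2 * ne * (1 - 1 / n)
        assert np.mean(ours) == pytest.approx(expected, rel=0.1)
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.1)


class TestSequences:
    def test_zero_branch_lengths_identical_sequences(self):
        t = PhyloTree.from_string("((A:0,B:0):0,C:0);")
        aln = simulate_sequences(t, 50, seed=1)
        assert len(set(aln.seqs)) == 1

    def test_determinism(self):
        t = PhyloTree.from_string("((A:0.1,B:0.1):0.1,C:0.2);")
        a = simulate_sequences(t, 100, seed=9)
        b = simulate_sequences(t, 100, seed=9)
        assert a.seqs == b.seqs

    @pytest.mark.parametrize("model", ["JC69", "HKY85"])
    def test_expected_divergence(self, model):
        # two tips separated by 2t: JC mismatch (3/4)(1-exp(-8t/3));
        # HKY85 with equal frequencies and normalised rate matches too
        t = 0.05
        tree = PhyloTree.from_string(f"(x:{t},y:{t});")
        aln = simulate_sequences(tree, 30000, model=model, seed=4)
        obs = pairwise_differences(aln.sequence("x"), aln.sequence("y")) / 30000
        if model == "JC69":
            expected = 0.75 * (1 - math.exp(-8 * t / 3))
            assert obs == pytest.approx(expected, abs=3 * 0.0017)
        else:
            assert 0.05 < obs < 0.14  # near 2t with multiple-hit correction


class TestGenerateDataset:
    def test_paper_shaped_geometry(self):
        ds = generate_dataset(preset("paper_shaped", seed=2))
        assert ds.alignment.length == 1464
        assert ds.alignment.partitions["trnLF"] == (0, 402)
        assert ds.alignment.partitions["ITS"] == (402, 1464)
        assert set(ds.alignment.ids) == set(ds.truth)
        assert set(ds.analysis_tree.tips()) == set(ds.truth)

    def test_null_preset_single_species(self):
        ds = generate_dataset(preset("null", seed=2))
        assert ds.k_true == 1
        assert ds.alignment.nseq == 20

    def test_bit_reproducible(self):
        a = generate_dataset(preset("deep4", seed=13))
        b = generate_dataset(preset("deep4", seed=13))
        assert a.alignment.seqs == b.alignment.seqs
        assert a.analysis_tree.to_string() == b.analysis_tree.to_string()
        c = generate_dataset(preset("deep4", seed=14))
        assert c.alignment.seqs != a.alignment.seqs

    def test_truth_support_annotation(self):
        ds = generate_dataset(preset("deep4", seed=2))
        by_sp = {}
        for acc, sp in ds.truth.items():
            by_sp.setdefault(sp, set()).add(acc)
        for node in ds.analysis_tree.tree.preorder_internal_node_iter():
            clade = PhyloTree.clade_tips(node)
            bs, pp = get_support(node)
            is_union = any(
                clade == frozenset().union(*combo)
                for r in (1, 2, 3, 4)
                for combo in _combos(list(by_sp.values()), r)
            )
            if bs == 100.0:
                assert is_union
            elif not is_union:
                assert bs is None

    def test_unlinked_loci_differ(self):
        from dataclasses import replace

        cfg = replace(preset("deep4", seed=3), linked_loci=False)
        ds = generate_dataset(cfg)
        assert (
            ds.gene_trees["trnLF"].to_string()
            != ds.gene_trees["ITS"].to_string()
        )

    def test_writes_plain_text_bundle(self, tmp_path):
        ds = generate_dataset(preset("null", seed=1))
        ds.write(tmp_path)
        assert (tmp_path / "alignment.fasta").exists()
        assert (tmp_path / "analysis_tree.nwk").exists()
        truth = (tmp_path / "truth.tsv").read_text().splitlines()
        assert len(truth) == 21  # header + 20 accessions


def _combos(groups, r):
    import itertools

    return itertools.combinations(groups, r)
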
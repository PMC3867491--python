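import itertools

import numpy as np
import pytest

from motudelim.simdata import simulate_gene_tree, simulate_species_tree
from motudelim.treeio import (
    Alignment,
    AlignmentError,
    PhyloTree,
    TreeError,
    detect_conflicts,
    get_support,
    read_alignment,
)


class TestReadTree:
    def test_bootstrap_label(self, toy_tree):
        assert set(toy_tree.tips()) == {"A", "B", "C"}
        node = toy_tree.mrca({"A", "B"})
        assert get_support(node) == (95.0, None)

    def test_absent_support(self):
        t = PhyloTree.from_string("((A:1,B:1):1,C:2);")
        assert get_support(t.mrca({"A", "B"})) == (None, None)

    def test_posterior_comment(self):
        t = PhyloTree.from_string("((A:1,B:1)[&posterior=0.98]:1,C:2);")
        assert get_support(t.mrca({"A", "B"})) == (None, 0.98)

    def test_combined_label(self):
        t = PhyloTree.from_string("((A:1,B:1)95/0.98:1,C:2);")
        assert get_support(t.mrca({"A", "B"})) == (95.0, 0.98)

    def test_label_as_posterior(self):
        t = PhyloTree.from_string(
            "((A:1,B:1)0.98:1,C:2);", label_as="posterior"
        )
        assert get_support(t.mrca({"A", "B"})) == (None, 0.98)

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "((A:1,A:1):1,C:2);", "((A:-1,B:1):1,C:2);"],
        ids=["unbalanced", "duplicate-tip", "negative-length"],
    )
    def test_rejects_malformed(self, bad):
        with pytest.raises(TreeError):
            PhyloTree.from_string(bad)

    def test_roundtrip_preserves_structure(self):
        rng = np.random.default_rng(4)
        sp = simulate_species_tree(6, 5.0, rng=rng)
        text = sp.to_string()
        again = PhyloTree.from_string(text)
        assert set(again.tips()) == set(sp.tips())
        for a, b in itertools.combinations(sorted(sp.tips()), 2):
            assert again.patristic_distance(a, b) == pytest.approx(
                sp.patristic_distance(a, b), abs=1e-9
            )

    def test_roundtrip_preserves_support(self):
        t = PhyloTree.from_string("((A:1,B:1)95/0.98:1,(C:1,D:1)88:1);")
        again = PhyloTree.from_string(t.to_string())
        assert get_support(again.mrca({"A", "B"})) == (95.0, 0.98)
        assert get_support(again.mrca({"C", "D"})) == (88.0, None)


class TestPrune:
    def test_prune_one_tip(self, toy_tree):
        pruned = toy_tree.prune_tips({"C"})
        assert set(pruned.tips()) == {"A", "B"}
        assert pruned.patristic_distance("A", "B") == pytest.approx(2.0)

    def test_prune_nothing_is_identity(self, toy_tree):
        pruned = toy_tree.prune_tips(set())
        assert set(pruned.tips()) == set(toy_tree.tips())
        assert pruned.patristic_distance("A", "C") == pytest.approx(4.0)

    def test_prune_sums_suppressed_branches(self):
        t = PhyloTree.from_string("(((A:1,B:1):2,C:1):3,(D:1,E:1):1);")
        pruned = t.prune_tips({"C"})
        # the unary node above {A,B} collapses, 2 + 3 = 5 on the path
        assert pruned.patristic_distance("A", "D") == pytest.approx(1 + 2 + 3 + 1 + 1)

    def test_prune_too_many(self, toy_tree):
        with pytest.raises(TreeError):
            toy_tree.prune_tips({"A", "B"})

    def test_prune_unknown(self, toy_tree):
        with pytest.raises(TreeError):
            toy_tree.prune_tips({"Z"})

    def test_disjoint_prunes_commute(self):
        rng = np.random.default_rng(11)
        sp = simulate_species_tree(8, 5.0, rng=rng)
        tips = sorted(sp.tips())
        s1, s2 = {tips[0], tips[3]}, {tips[5]}
        ab = sp.prune_tips(s1).prune_tips(s2)
        ba = sp.prune_tips(s2).prune_tips(s1)
        assert set(ab.tips()) == set(ba.tips())
        for a, b in itertools.combinations(sorted(ab.tips()), 2):
            assert ab.patristic_distance(a, b) == pytest.approx(
                ba.patristic_distance(a, b)
            )


class TestPatristic:
    def test_hand_path_sums(self, toy_tree):
        assert toy_tree.patristic_distance("A", "B") == pytest.approx(2.0)
        assert toy_tree.patristic_distance("A", "A") == 0.0
        assert toy_tree.patristic_distance("A", "C") == pytest.approx(4.0)

    def test_unknown_tip(self, toy_tree):
        with pytest.raises(TreeError):
            toy_tree.patristic_distance("A", "Z")

    def test_symmetry_and_four_point(self):
        rng = np.random.default_rng(3)
        sp = simulate_species_tree(1, 5.0, rng=rng)
        gt = simulate_gene_tree(sp, 0.01, {"sp1": 6}, rng=rng)
        tips = sorted(gt.tips())
        d = {
            (a, b): gt.patristic_distance(a, b)
            for a in tips
            for b in tips
        }
        for a, b in itertools.combinations(tips, 2):
            assert d[a, b] == pytest.approx(d[b, a])
            assert d[a, b] > 0
        for q in itertools.combinations(tips, 4):
            a, b, c, e = q
            sums = sorted(
                [d[a, b] + d[c, e], d[a, c] + d[b, e], d[a, e] + d[b, c]]
            )
            assert sums[1] == pytest.approx(sums[2], rel=1e-9)


class TestDetectConflicts:
    def test_identical_trees(self, symmetric_tree):
        t = PhyloTree.from_string("((A:1,B:1)99:2,(C:1,D:1)99:2);")
        assert detect_conflicts(t, t, 70) == set()

    def test_below_threshold_ignored(self):
        a = PhyloTree.from_string("(((A:1,B:1)50:1,C:1):1,(D:1,E:1):1);")
        b = PhyloTree.from_string("(((A:1,C:1)60:1,B:1):1,(D:1,E:1):1);")
        assert detect_conflicts(a, b, 70) == set()

    def test_conflicting_supported_splits(self):
        a = PhyloTree.from_string("((A:1,B:1)95:1,(C:1,D:1)95:1);")
        b = PhyloTree.from_string("((A:1,C:1)95:1,(B:1,D:1)95:1);")
        conflicts = detect_conflicts(a, b, 70)
        assert len(conflicts) >= 1
        pair = next(iter(conflicts))
        assert frozenset({"A", "B"}) in pair or frozenset({"C", "D"}) in pair

    def test_disjoint_tip_sets(self):
        a = PhyloTree.from_string("((A:1,B:1):1,C:2);")
        b = PhyloTree.from_string("((X:1,Y:1):1,Z:2);")
        with pytest.raises(TreeError):
            detect_conflicts(a, b, 70)


class TestAlignmentIO:
    def test_read_fasta(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1\nACGTACGTAC\n>s2\nacgtacgtac\n>s3\nACGTACGTTT\n")
        aln = read_alignment(p, format="fasta")
        assert aln.nseq == 3 and aln.length == 10
        assert aln.sequence("s2") == "ACGTACGTAC"  # upper-cased

    def test_read_nexus_charsets(self, tmp_path):
        p = tmp_path / "x.nex"
        p.write_text(
            "#NEXUS\nbegin data;\ndimensions ntax=2 nchar=8;\n"
            "format datatype=dna missing=? gap=-;\nmatrix\n"
            "s1 ACGTACGT\ns2 ACGTACTT\n;\nend;\n"
            "begin sets;\ncharset one = 1-4;\ncharset two = 5-8;\nend;\n"
        )
        aln = read_alignment(p, format="nexus")
        assert aln.nseq == 2
        assert aln.partitions == {"one": (0, 4), "two": (4, 8)}

    def test_ragged_reports_offender(self):
        with pytest.raises(AlignmentError, match="short"):
            Alignment(ids=("ok", "short"), seqs=("ACGT", "ACG"))

    def test_illegal_character_reports_position(self):
        with pytest.raises(AlignmentError, match="column 3"):
            Alignment(ids=("s1",), seqs=("AC!T",))
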
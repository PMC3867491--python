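import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motudelim.delim_stats import (
    NotMonophyleticError,
    av_ma,
    intra_inter,
    pab_enumerated,
    pid,
    rodrigo_prd,
    rosenberg_pab,
    rosenberg_pab_exact,
    simulate_null_R,
)
from motudelim.simdata import simulate_gene_tree, simulate_species_tree
from motudelim.treeio import PhyloTree, TreeError


def literal_history_counts(a, b):
    """Count labeled histories with/without reciprocal monophyly.

    True brute force: explores every sequence of pairwise merges of the
    lineage sets; no probability shortcuts.  Feasible for a+b <= 6.
    """
    start = tuple(
        [frozenset({("A", i)}) for i in range(a)]
        + [frozenset({("B", i)}) for i in range(b)]
    )
    full_a = frozenset(("A", i) for i in range(a))
    full_b = frozenset(("B", i) for i in range(b))

    def explore(lineages, seen_a, seen_b):
        if len(lineages) == 1:
            return 1, int(seen_a and seen_b)
        total = good = 0
        for i, j in itertools.combinations(range(len(lineages)), 2):
            merged = lineages[i] | lineages[j]
            rest = tuple(
                l for k, l in enumerate(lineages) if k not in (i, j)
            ) + (merged,)
            t, g = explore(
                rest,
                seen_a or merged == full_a,
                seen_b or merged == full_b,
            )
            total += t
            good += g
        return total, good

    return explore(start, a == 1, b == 1)


class TestRosenbergPab:
    def test_two_singletons_always_monophyletic(self):
        assert rosenberg_pab(1, 1) == 1.0

    def test_enumerated_spot_values(self):
        assert rosenberg_pab_exact(2, 1) == Fraction(1, 3)
        assert rosenberg_pab_exact(2, 2) == Fraction(1, 9)

    def test_closed_form_equals_history_recursion_up_to_8(self):
        for n in range(2, 9):
            for a in range(1, n):
                assert rosenberg_pab_exact(a, n - a) == pab_enumerated(a, n - a)

    def test_recursion_matches_literal_enumeration(self):
        for a, b in [(2, 1), (2, 2), (3, 2), (4, 2), (3, 3)]:
            total, good = literal_history_counts(a, b)
            assert pab_enumerated(a, b) == Fraction(good, total)

    def test_symmetry_and_monotonicity(self):
        for a in range(1, 6):
            for b in range(1, 6):
                assert rosenberg_pab_exact(a, b) == rosenberg_pab_exact(b, a)
                if a + b >= 3:
                    assert rosenberg_pab_exact(a + 1, b) < rosenberg_pab_exact(a, b)

    def test_significance_threshold_regime(self):
        # large balanced groups are far below the 1e-5 distinctness cut
        assert rosenberg_pab(10, 10) < 1e-5
        assert rosenberg_pab(3, 3) > 1e-5

    def test_topology_null_variant(self):
        assert rosenberg_pab(2, 1, null="topologies") == pytest.approx(1 / 3)
        assert rosenberg_pab(2, 2, null="topologies") == pytest.approx(1 / 15)

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            rosenberg_pab(0, 3)

    def test_overflow_safe_for_large_groups(self):
        p = rosenberg_pab(600, 500)
        assert 0.0 <= p < 1e-300 or p == 0.0


class TestAvMa:
    def test_singleton_clade_is_zero(self, toy_tree):
        assert av_ma(toy_tree, {"A"}) == 0.0

    def test_ultrametric_clade_equals_depth(self, symmetric_tree):
        assert av_ma(symmetric_tree, {"A", "B"}) == pytest.approx(1.0)

    def test_mean_of_unequal_paths(self):
        t = PhyloTree.from_string("((A:1,B:3):1,C:2);")
        assert av_ma(t, {"A", "B"}) == pytest.approx(2.0)

    def test_non_monophyletic_reports_spanning_clade(self, toy_tree):
        with pytest.raises(NotMonophyleticError) as err:
            av_ma(toy_tree, {"A", "C"})
        assert err.value.spanning == {"A", "B", "C"}


class TestIntraInter:
    def test_hand_path_sums(self, symmetric_tree):
        intra, inter, ratio = intra_inter(symmetric_tree, {"A", "B"})
        assert intra == pytest.approx(2.0)
        assert inter == pytest.approx(6.0)
        assert ratio == pytest.approx(1 / 3)

    def test_identical_tips_give_zero_intra(self):
        t = PhyloTree.from_string("((A:0,B:0):1,C:2);")
        intra, inter, ratio = intra_inter(t, {"A", "B"})
        assert intra == 0.0 and ratio == 0.0

    def test_scale_invariance_of_ratio(self, symmetric_tree):
        scaled = PhyloTree.from_string("((A:10,B:10):20,(C:10,D:10):20);")
        assert intra_inter(symmetric_tree, {"A", "B"})[2] == pytest.approx(
            intra_inter(scaled, {"A", "B"})[2]
        )

    def test_singleton_clade_rejected(self, toy_tree):
        with pytest.raises(TreeError):
            intra_inter(toy_tree, {"A"})


class TestRodrigoPrd:
    def test_zero_stem_never_distinct(self):
        t = PhyloTree.from_string("(((A:1,B:1):0,C:1):1,D:2);")
        res = rodrigo_prd(t, {"A", "B"}, reps=200, seed=1)
        assert res.observed_R == 1.0
        assert res.p == 1.0

    def test_identical_tips_on_long_stem_maximally_distinct(self):
        t = PhyloTree.from_string("(((A:0,B:0):5,C:1):1,D:2);")
        res = rodrigo_prd(t, {"A", "B"}, reps=200, seed=1)
        assert res.observed_R == 0.0
        assert res.p <= 0.01

    def test_root_clade_rejected(self, toy_tree):
        with pytest.raises(TreeError):
            rodrigo_prd(toy_tree, {"A", "B", "C"}, reps=200, seed=1)

    def test_seeded_reproducibility(self, symmetric_tree):
        r1 = rodrigo_prd(symmetric_tree, {"A", "B"}, reps=300, seed=9)
        r2 = rodrigo_prd(symmetric_tree, {"A", "B"}, reps=300, seed=9)
        assert r1.p == r2.p and r1.observed_R == r2.observed_R

    def test_mc_error_shrinks_with_reps(self, symmetric_tree):
        small = rodrigo_prd(symmetric_tree, {"A", "B"}, reps=200, seed=3)
        large = rodrigo_prd(symmetric_tree, {"A", "B"}, reps=800, seed=3)
        assert large.mc_error < small.mc_error

    def test_null_R_is_scale_free_ratio_of_heights(self):
        rng = np.random.default_rng(0)
        vals = simulate_null_R(10, 50, rng)
        assert ((vals > 0) & (vals < 1)).all()


class TestPid:
    def test_tight_distant_clade_fully_identifiable(self):
        t = PhyloTree.from_string(
            "(((A:0.1,B:0.1):5,(C:0.1,D:0.1):5):1,(E:1,F:1):1);"
        )
        res = pid(t, {"A", "B"}, mode="strict", resamples=200, seed=0)
        assert res.p == 1.0
        assert res.ci[0] <= res.p <= res.ci[1]

    def test_singleton_untestable(self, toy_tree):
        res = pid(toy_tree, {"A"}, resamples=200, seed=0)
        assert res.untestable and res.p is None

    def test_liberal_at_least_strict(self):
        rng = np.random.default_rng(6)
        sp = simulate_species_tree(1, 5.0, rng=rng)
        gt = simulate_gene_tree(sp, 0.01, {"sp1": 10}, rng=rng)
        tips = sorted(gt.tips())
        node = gt.mrca({tips[0], tips[1]})
        clade = PhyloTree.clade_tips(node)
        if len(clade) >= 2 and len(clade) < len(tips):
            strict = pid(gt, clade, "strict", resamples=200, seed=1)
            liberal = pid(gt, clade, "liberal", resamples=200, seed=1)
            assert liberal.p >= strict.p

    def test_intermingled_group_poorly_identifiable(self):
        # an arbitrary half of a panmictic sample is not genealogically
        # exclusive, so strict identification must fail for some members
        rng = np.random.default_rng(12)
        sp = simulate_species_tree(1, 5.0, rng=rng)
        values = []
        for _ in range(10):
            gt = simulate_gene_tree(sp, 0.005, {"sp1": 12}, rng=rng)
            tips = sorted(gt.tips())
            group = set(rng.choice(tips, size=6, replace=False))
            values.append(pid(gt, group, "strict", resamples=100, seed=0).p)
        assert np.mean(values) < 0.9
        assert min(values) < 1.0
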
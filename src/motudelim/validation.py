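"""Self-validation experiments for the delimitation pipeline.

Each function here recomputes, from scratch, one of the package's
calibration or recovery quantities: exactness of the reciprocal-
monophyly probability against enumeration, agreement of the closed-form
connection limit with its Monte-Carlo oracle, uniformity of P(RD) under
the coalescent null, type-I control and parameter recovery of the full
pipeline on synthetic data, and the finite-sites simulator against the
Jukes-Cantor closed form.  The functions are deliberately seed-driven
and return plain numbers so that both the test suite and the acceptance
script can call them.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from .delim_stats import (
    pab_enumerated,
    rosenberg_pab_exact,
    simulate_null_R,
)
from .parsnet import connection_limit, mc_connection_limit
from .pipeline import DelimitationConfig, delimit
from .simdata import generate_dataset, preset, simulate_sequences
from .alignment_stats import pairwise_differences

__all__ = [
    "pab_enumeration_max_error",
    "connection_limit_comparison",
    "prd_calibration",
    "null_type1_experiment",
    "deep4_recovery_experiment",
    "jc_divergence_check",
]


def _spawn_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def pab_enumeration_max_error(max_n=8):
    """Largest |closed form - enumeration| over all (a, b) with a+b <= max_n.

    Both sides are exact rationals, so anything but zero is a defect.
    """
    worst = Fraction(0)
    for n in range(2, max_n + 1):
        for a in range(1, n):
            b = n - a
            diff = abs(rosenberg_pab_exact(a, b) - pab_enumerated(a, b))
            worst = max(worst, diff)
    return float(worst)


def connection_limit_comparison(
    lengths=(200, 400, 1000, 1500), alpha=0.95, seed=0, pairs_per_t=1500
):
    """Closed-form vs Monte-Carlo 95% connection limits per length.

    Returns (dict L -> (closed, mc), max absolute difference in steps).
    """
    seeds = _spawn_seeds(seed, len(lengths))
    out = {}
    worst = 0
    for L, s in zip(lengths, seeds):
        closed = connection_limit(L, alpha=alpha)
        mc = mc_connection_limit(L, alpha=alpha, seed=s, pairs_per_t=pairs_per_t)
        out[L] = (closed, mc)
        worst = max(worst, abs(closed - mc))
    return out, worst


def prd_calibration(trials=500, n_tips=20, reps=200, threshold=0.05, seed=0):
    """Fraction of null-coalescent clades with P(RD) <= threshold.

    Each trial simulates one observed coalescent tree, samples one of its
    internal non-root clades uniformly (via the clade-R pool), and ranks
    its R against a freshly simulated null of *reps* trees.  Under the
    null the P(RD) values are approximately uniform, so the fraction
    should sit near *threshold*.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(trials):
        observed_pool = simulate_null_R(n_tips, 1, rng)
        r_obs = observed_pool[rng.integers(len(observed_pool))]
        null = simulate_null_R(n_tips, reps, rng)
        p = float(np.mean(null <= r_obs))
        hits += p <= threshold
    return hits / trials


def _experiment_config(seed, prd_reps=200):
    return DelimitationConfig(prd_reps=prd_reps, pid_resamples=200, seed=seed)


def null_type1_experiment(replicates=100, seed=0, prd_reps=200):
    """Proportion of single-species datasets delimited as exactly one unit.

    A delimited unit is an accepted MOTU or an untested single-haplotype
    candidate; under the null the whole sample should come back as one
    unit covering every tip (no spurious splits, nothing unassigned).
    """
    seeds = _spawn_seeds(seed, replicates)
    ok = 0
    for s in seeds:
        ds = generate_dataset(preset("null", seed=s))
        res = delimit(ds.analysis_tree, ds.alignment, _experiment_config(s, prd_reps))
        part = res.partition
        ok += part.delimited_units() == {frozenset(ds.truth)} and not part.unassigned
    return ok / replicates


def deep4_recovery_experiment(replicates=50, seed=0, prd_reps=200):
    """Recovery rates on four deeply divergent species (T = 20 Ne).

    Returns (fraction of replicates whose delimited units match the true
    species partition exactly, fraction whose parsimony-network
    components are independent per species: every species' haplotypes in
    exactly one component shared with no other species).
    """
    seeds = _spawn_seeds(seed, replicates)
    ok_motu = 0
    ok_net = 0
    for s in seeds:
        ds = generate_dataset(preset("deep4", seed=s))
        res = delimit(ds.analysis_tree, ds.alignment, _experiment_config(s, prd_reps))
        truth_groups = {}
        for acc, sp in ds.truth.items():
            truth_groups.setdefault(sp, set()).add(acc)
        truth_sets = {frozenset(v) for v in truth_groups.values()}
        ok_motu += res.partition.delimited_units() == truth_sets
        a2h = res.haplotype_table.accession_to_haplotype()
        comp_of = res.network.component_of()
        sp_comps = [
            {comp_of[a2h[acc]] for acc in group} for group in truth_groups.values()
        ]
        ok_net += all(len(c) == 1 for c in sp_comps) and len(
            set().union(*sp_comps)
        ) == len(sp_comps)
    return ok_motu / replicates, ok_net / replicates


def jc_divergence_check(t=0.05, length=100_000, seed=0):
    """Observed vs expected mismatch fraction for two tips at divergence 2t.

    Expected proportion is (3/4)(1 - exp(-8t/3)); returns
    (observed, expected, z) where z is the deviation in binomial SEs.
    """
    import dendropy

    from .treeio import PhyloTree

    tree = dendropy.Tree()
    tree.is_rooted = True
    ns = tree.taxon_namespace
    for lab in ("x", "y"):
        leaf = dendropy.Node()
        leaf.taxon = ns.new_taxon(label=lab)
        leaf.edge.length = t
        tree.seed_node.add_child(leaf)
    ptree = PhyloTree(tree=tree)
    aln = simulate_sequences(ptree, length, model="JC69", seed=seed)
    observed = pairwise_differences(aln.sequence("x"), aln.sequence("y")) / length
    expected = 0.75 * (1.0 - math.exp(-8.0 * t / 3.0))
    se = math.sqrt(expected * (1 - expected) / length)
    z = (observed - expected) / se
    return observed, expected, z
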
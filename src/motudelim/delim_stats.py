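"""Per-clade distinctiveness statistics.

Implements the coalescent-based measures used to decide whether a clade
on a phylogram is more distinct than random genealogical structure would
produce:

* ``rosenberg_pab`` -- probability that two groups of sizes ``a`` and
  ``b`` are reciprocally monophyletic on a random coalescent genealogy
  (equiprobable labeled histories).  Closed form
  ``2 a! b! (n-2)! / (n! (n-1)!)``, evaluated in exact rational
  arithmetic; an independent enumeration over labeled histories is
  provided for verification.  A uniform-labeled-topology null is
  available behind ``null="topologies"``.
* ``rodrigo_prd`` -- probability that a random coalescent clade is at
  least as "distinct" as the observed one, where distinctness is the
  scale-free ratio R = Av(MA) / (Av(MA) + stem length); small R means a
  shallow clade on a long stem.  The null distribution pools R over all
  internal non-root clades of simulated Kingman coalescent trees with
  the same tip count (on an ultrametric tree R reduces to the ratio of
  a node's height to its parent's height).
* ``pid`` -- probability of correct identification of an unknown query
  from the clade, operationalised as leave-one-out nearest-neighbour
  placement by patristic distance (strict: nearest tip inside the clade;
  liberal: inside the clade or its sister), with a nonparametric
  bootstrap CI over members.
* ``av_ma`` / ``intra_inter`` -- mean MRCA-to-member path length and the
  mean intra- vs inter-clade patristic distances.

A clade with P(AB) < 1e-5 or P(RD) <= 0.05 is flagged genetically
distinct at the default thresholds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .treeio import PhyloTree, TreeError

__all__ = [
    "rosenberg_pab",
    "rosenberg_pab_exact",
    "pab_enumerated",
    "av_ma",
    "intra_inter",
    "rodrigo_prd",
    "simulate_null_R",
    "pid",
    "PrdResult",
    "PidResult",
    "CladeTest",
    "NotMonophyleticError",
    "is_significant",
]


class NotMonophyleticError(TreeError):
    def __init__(self, tips, spanning):
        self.tips = frozenset(tips)
        self.spanning = frozenset(spanning)
        extra = sorted(self.spanning - self.tips)
        super().__init__(
            f"tip set is not monophyletic; minimal spanning clade adds {extra}"
        )


# ---------------------------------------------------------------------------
# Rosenberg's P(AB)
# ---------------------------------------------------------------------------


def rosenberg_pab_exact(a, b):
    """Exact P(AB) under the coalescent (labeled histories) null."""
    if a < 1 or b < 1:
        raise ValueError("group sizes must be >= 1")
    n = a + b
    return Fraction(
        2 * math.factorial(a) * math.factorial(b) * math.factorial(n - 2),
        math.factorial(n) * math.factorial(n - 1),
    )


def _double_factorial(k):
    return math.prod(range(k, 0, -2)) if k > 0 else 1


def rosenberg_pab(a, b, null="coalescent"):
    """P(AB): probability of reciprocal monophyly of groups of sizes a, b.

    ``null="coalescent"`` (default) assumes equiprobable labeled
    histories; ``null="topologies"`` assumes uniform rooted labeled
    topologies.
    """
    if null == "coalescent":
        return float(rosenberg_pab_exact(a, b))
    if null == "topologies":
        if a < 1 or b < 1:
            raise ValueError("group sizes must be >= 1")
        n = a + b
        return float(
            Fraction(
                _double_factorial(2 * a - 3) * _double_factorial(2 * b - 3),
                _double_factorial(2 * n - 3),
            )
        )
    raise ValueError(f"unknown null model: {null}")


@lru_cache(maxsize=None)
def _pab_recursion(a, b):
    if a == 1 and b == 1:
        return Fraction(1)
    total = Fraction((a + b) * (a + b - 1), 2)
    acc = Fraction(0)
    if a >= 2:
        acc += Fraction(a * (a - 1), 2) * _pab_recursion(a - 1, b)
    if b >= 2:
        acc += Fraction(b * (b - 1), 2) * _pab_recursion(a, b - 1)
    return acc / total

def pab_enumerated(a, b):
    """P(AB) by exact enumeration over coalescent labeled histories.

    At every coalescence a uniformly random lineage pair merges;
    reciprocal monophyly requires all merges to stay within a group until
    each group has a single ancestor.  Exact rational arithmetic;
    independent of the closed form.
    """
    if a < 1 or b < 1:
        raise ValueError("group sizes must be >= 1")
    return _pab_recursion(a, b)


# ---------------------------------------------------------------------------
# Clade geometry
# ---------------------------------------------------------------------------


def _clade_node(tree, clade):
    clade = frozenset(clade)
    if not clade:
        raise TreeError("empty clade")
    node = tree.mrca(clade)
    spanning = PhyloTree.clade_tips(node) if not node.is_leaf() else frozenset(
        [node.taxon.label]
    )
    if spanning != clade:
        raise NotMonophyleticError(clade, spanning)
    return node


def av_ma(tree, clade):
    """Mean path length from the clade's MRCA to its member tips."""
    clade = frozenset(clade)
    node = _clade_node(tree, clade)
    if node.is_leaf():
        return 0.0
    tree._require_lengths()
    total = 0.0
    for leaf in node.leaf_iter():
        d = 0.0
        nd = leaf
        while nd is not node:
            d += nd.edge.length
            nd = nd.parent_node
        total += d
    return total / len(clade)


def intra_inter(tree, clade):
    """(mean intra-clade, mean clade-to-sister, intra/inter ratio).

    The ratio is inf (flagged by the caller) when inter is zero.
    """
    clade = frozenset(clade)
    if len(clade) < 2:
        raise TreeError("intra/inter requires a clade of >= 2 tips")
    node = _clade_node(tree, clade)
    sister = tree.sister_tips(node)
    if not sister:
        raise TreeError("clade has an empty sister group")
    labels, mat = tree.distance_matrix()
    idx = {lab: i for i, lab in enumerate(labels)}
    ci = [idx[t] for t in sorted(clade)]
    si = [idx[t] for t in sorted(sister)]
    intra = float(np.mean([mat[i, j] for i, j in itertools.combinations(ci, 2)]))
    inter = float(np.mean([mat[i, j] for i in ci for j in si]))
    ratio = math.inf if inter == 0 else intra / inter
    return intra, inter, ratio


# ---------------------------------------------------------------------------
# Rodrigo's P(RD)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrdResult:
    p: float
    mc_error: float
    reps: int
    seed: int
    observed_R: float

    def __float__(self):
        return self.p


def simulate_null_R(n_tips, reps, rng):
    """R values over all internal non-root clades of Kingman trees.

    Simulates ``reps`` n-tip coalescent genealogies (rate 1 per lineage
    pair; R is scale-free so the rate is irrelevant) and collects, for
    every internal node that is not the root, the ratio of its height to
    its parent's height -- which equals Av(MA)/(Av(MA)+stem) on an
    ultrametric tree.
    """
    if n_tips < 3:
        raise ValueError("null trees need >= 3 tips")
    out = []
    for _ in range(reps):
        heights = [0.0] * n_tips  # active lineage node heights; leaves at 0
        t = 0.0
        k = n_tips
        while k > 1:
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            hi, hj = heights[i], heights[j]
            for h in (hi, hj):
                if h > 0.0:  # internal child: record R = h_child / h_parent
                    out.append(h / t)
            # replace i with merged node, remove j
            heights[i] = t
            heights[j] = heights[k - 1]
            heights.pop()
            k -= 1
    return np.asarray(out)


def rodrigo_prd(tree, clade, reps=1000, seed=0, null_R=None):
    """P(RD): fraction of null coalescent clades at least as distinct.

    The observed statistic is R = Av(MA)/(Av(MA) + s) with s the length
    of the branch subtending the clade; the null pools R over all
    internal clades of ``reps`` simulated Kingman trees with the same
    total tip count as *tree*.  Pass ``null_R`` to reuse a simulated null
    across clades of the same tree.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    clade = frozenset(clade)
    node = _clade_node(tree, clade)
    if node.parent_node is None:
        raise TreeError("P(RD) is undefined for the root clade")
    tree._require_lengths()
    s = node.edge.length
    ama = av_ma(tree, clade)
    if ama == 0.0 and s == 0.0:
        r_obs = 1.0
    else:
        r_obs = ama / (ama + s)
    if null_R is None:
        rng = np.random.default_rng(seed)
        null_R = simulate_null_R(len(tree), reps, rng)
    p = float(np.mean(null_R <= r_obs))
    mc_error = math.sqrt(max(p * (1 - p), 1.0 / len(null_R)) / len(null_R))
    return PrdResult(p=p, mc_error=mc_error, reps=reps, seed=seed, observed_R=r_obs)


# ---------------------------------------------------------------------------
# P ID (strict / liberal)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PidResult:
    mode: str
    p: float | None
    ci: tuple | None
    resamples: int
    untestable: bool = False

    def __float__(self):
        if self.p is None:
            raise ValueError("untestable P ID result has no point estimate")
        return self.p


def pid(tree, clade, mode="strict", resamples=1000, seed=0):
    """Leave-one-out probability of correct identification for a group.

    strict: a member's nearest non-self tip lies inside the group;
    liberal: inside the group or the sister of its spanning clade.  Ties
    in the minimum distance count as correct.  Singleton groups are
    untestable.  The group need not be monophyletic -- identification of
    a possibly non-exclusive set is exactly what the measure probes.
    """
    if mode not in ("strict", "liberal"):
        raise ValueError(f"unknown mode: {mode}")
    if resamples < 100:
        raise ValueError("resamples must be >= 100")
    clade = frozenset(clade)
    if len(clade) < 2:
        return PidResult(mode=mode, p=None, ci=None, resamples=resamples,
                         untestable=True)
    node = tree.mrca(clade)
    allowed = set(clade)
    if mode == "liberal" and node.parent_node is not None:
        allowed |= tree.sister_tips(node)
    labels, mat = tree.distance_matrix()
    idx = {lab: i for i, lab in enumerate(labels)}
    allowed_idx = np.array([idx[t] for t in sorted(allowed)])
    outside_idx = np.array(
        [i for lab, i in idx.items() if lab not in allowed], dtype=int
    )
    correct = []
    for member in sorted(clade):
        mi = idx[member]
        inside = [i for i in allowed_idx if i != mi]
        d_in = mat[mi, inside].min()
        d_out = mat[mi, outside_idx].min() if len(outside_idx) else math.inf
        correct.append(1.0 if d_in <= d_out else 0.0)
    correct = np.asarray(correct)
    point = float(correct.mean())
    rng = np.random.default_rng(seed)
    boots = rng.choice(correct, size=(resamples, len(correct)), replace=True)
    means = boots.mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    ci = (min(float(lo), point), max(float(hi), point))
    return PidResult(mode=mode, p=point, ci=ci, resamples=resamples)


# ---------------------------------------------------------------------------
# Bundled per-clade test record
# ---------------------------------------------------------------------------


def is_significant(pab, prd, pab_threshold=1e-5, prd_threshold=0.05):
    """The joint distinctiveness rule: P(AB) < 1e-5 or P(RD) <= 0.05."""
    hit = False
    if pab_threshold is not None and pab is not None:
        hit = hit or (pab < pab_threshold)
    if prd_threshold is not None and prd is not None:
        hit = hit or (prd <= prd_threshold)
    return hit


@dataclass
class CladeTest:
    """Everything measured for one clade-vs-sister comparison."""

    label: str
    clade: frozenset
    sister: frozenset
    bootstrap: float | None = None
    posterior: float | None = None
    intra_dist: float | None = None
    inter_dist: float | None = None
    intra_inter_ratio: float | None = None
    av_ma: float | None = None
    pab: float | None = None
    prd: PrdResult | None = None
    pid_strict: PidResult | None = None
    pid_liberal: PidResult | None = None
    significant: bool = False

    @property
    def a(self):
        return len(self.clade)

    @property
    def b(self):
        return len(self.sister)


def clade_test(
    tree,
    clade,
    label="",
    prd_reps=1000,
    pid_resamples=200,
    seed=0,
    null_R=None,
    pab_threshold=1e-5,
    prd_threshold=0.05,
    compute_pid=True,
):
    """Run the full battery of distinctiveness statistics for one clade."""
    from .treeio import get_support

    clade = frozenset(clade)
    node = _clade_node(tree, clade)
    if node.parent_node is None:
        raise TreeError("cannot test the root clade against a sister")
    sister = tree.sister_tips(node)
    bs, pp = get_support(node)
    pab = rosenberg_pab(len(clade), len(sister))
    prd = rodrigo_prd(tree, clade, reps=prd_reps, seed=seed, null_R=null_R)
    intra = inter = ratio = None
    if len(clade) >= 2:
        intra, inter, ratio = intra_inter(tree, clade)
    result = CladeTest(
        label=label,
        clade=clade,
        sister=sister,
        bootstrap=bs,
        posterior=pp,
        intra_dist=intra,
        inter_dist=inter,
        intra_inter_ratio=ratio,
        av_ma=av_ma(tree, clade),
        pab=pab,
        prd=prd,
        significant=is_significant(pab, prd.p, pab_threshold, prd_threshold),
    )
    if compute_pid and len(clade) >= 2:
        result.pid_strict = pid(tree, clade, "strict", pid_resamples, seed)
        result.pid_liberal = pid(tree, clade, "liberal", pid_resamples, seed)
    return result
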
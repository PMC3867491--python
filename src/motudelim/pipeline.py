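"""Two-stage MOTU delimitation.

Stage 1 (*predefinition*): candidate MOTUs are the maximal clades of the
input phylogram that (i) meet the clade-support condition (bootstrap
and/or posterior thresholds) and (ii) are *network independent*: their
members' haplotypes form exactly one statistical-parsimony network
component shared with no outside accession.  Candidates whose members
collapse to a single haplotype cannot be tested with the coalescent
statistics and are reported as "untested".

Stage 2 (*tip-to-root*): every clade with two or more tips is tested
against its sister group with Rosenberg's P(AB) and Rodrigo's P(RD),
visiting nodes from the tips toward the root.  Clades are labelled
``<depth>-<index>`` in traversal order.

Acceptance: each testable candidate becomes one MOTU unless it contains
nested tip-to-root clades that pass both the support condition and the
distinctiveness rule (P(AB) < 1e-5 or P(RD) <= 0.05); in that case the
finest such clades replace it and any residual members form a sibling
MOTU.  MOTUs are therefore always disjoint clades (or flagged
singletons) of the input tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import haplotypes, parsnet
from .delim_stats import CladeTest, clade_test, simulate_null_R
from .haplotypes import CollapsePolicy
from .treeio import PhyloTree, TreeError, get_support

__all__ = [
    "DelimitationConfig",
    "MOTU",
    "MOTUPartition",
    "Candidate",
    "predefine_motus",
    "tip_to_root",
    "delimit",
    "DelimitationResult",
]


@dataclass(frozen=True)
class DelimitationConfig:
    bootstrap_threshold: float | None = 95.0
    posterior_threshold: float | None = 0.95
    support_mode: str = "or"  # "or" | "and" | "ignore"
    pab_threshold: float | None = 1e-5
    prd_threshold: float | None = 0.05
    prd_reps: int = 1000
    pid_resamples: int = 200
    compute_pid: bool = True
    alpha: float = 0.95
    connection_limit: int | None = None  # override computed limit
    collapse_policy: CollapsePolicy = field(default_factory=CollapsePolicy)
    outgroup: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.support_mode not in ("or", "and", "ignore"):
            raise ValueError(f"unknown support_mode: {self.support_mode}")
        if self.bootstrap_threshold is not None and not (
            0 <= self.bootstrap_threshold <= 100
        ):
            raise ValueError("bootstrap_threshold out of range")
        if self.posterior_threshold is not None and not (
            0 <= self.posterior_threshold <= 1
        ):
            raise ValueError("posterior_threshold out of range")
        if self.pab_threshold is None and self.prd_threshold is None:
            raise ValueError(
                "at least one of pab_threshold / prd_threshold must be set"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha out of range")

    def support_ok(self, node):
        if self.support_mode == "ignore":
            return True
        bs, pp = get_support(node)
        bs_ok = (
            self.bootstrap_threshold is not None
            and bs is not None
            and bs >= self.bootstrap_threshold
        )
        pp_ok = (
            self.posterior_threshold is not None
            and pp is not None
            and pp >= self.posterior_threshold
        )
        if self.support_mode == "and":
            return bs_ok and pp_ok
        return bs_ok or pp_ok


@dataclass
class Candidate:
    """A predefined MOTU candidate (stage 1)."""

    tips: frozenset
    component: str | None
    n_haplotypes: int
    bootstrap: float | None
    posterior: float | None
    testable: bool

    def __len__(self):
        return len(self.tips)


@dataclass
class MOTU:
    motu_id: str
    tips: frozenset
    source: str  # "predefined" | "tip-to-root" | "residual"
    component: str | None = None
    clade_test: CladeTest | None = None

    def __len__(self):
        return len(self.tips)


@dataclass
class MOTUPartition:
    motus: list
    untested: list  # single-haplotype Candidates
    unassigned: list  # tip labels in no MOTU and no untested candidate

    @property
    def n_motus(self):
        return len(self.motus)

    def delimited_units(self):
        """Tip sets of all delimited units: accepted MOTUs plus untested
        single-haplotype candidates (which are MOTUs the coalescent tests
        cannot score, mirroring how single-haplotype clades are reported)."""
        return {frozenset(m.tips) for m in self.motus} | {
            frozenset(c.tips) for c in self.untested
        }


@dataclass
class DelimitationResult:
    partition: MOTUPartition
    candidates: list
    clade_tests: list
    network: parsnet.ParsimonyNetwork
    haplotype_table: haplotypes.HaplotypeTable
    config: DelimitationConfig

    def report(self):
        """Evidence table, one row per MOTU / untested candidate."""
        rows = []
        for m in self.partition.motus:
            ct = m.clade_test
            rows.append(
                {
                    "motu": m.motu_id,
                    "n_tips": len(m.tips),
                    "source": m.source,
                    "network_component": m.component,
                    "bootstrap": ct.bootstrap if ct else None,
                    "posterior": ct.posterior if ct else None,
                    "intra_dist": ct.intra_dist if ct else None,
                    "intra_inter": ct.intra_inter_ratio if ct else None,
                    "av_ma": ct.av_ma if ct else None,
                    "pab": ct.pab if ct else None,
                    "prd": ct.prd.p if ct and ct.prd else None,
                    "pid_strict": (
                        ct.pid_strict.p if ct and ct.pid_strict else None
                    ),
                    "pid_liberal": (
                        ct.pid_liberal.p if ct and ct.pid_liberal else None
                    ),
                    "significant": ct.significant if ct else None,
                    "members": ";".join(sorted(m.tips)),
                }
            )
        for c in self.partition.untested:
            rows.append(
                {
                    "motu": "untested",
                    "n_tips": len(c.tips),
                    "source": "predefined",
                    "network_component": c.component,
                    "bootstrap": c.bootstrap,
                    "posterior": c.posterior,
                    "members": ";".join(sorted(c.tips)),
                }
            )
        return pd.DataFrame(rows)

    def clade_table(self):
        """Raw tip-to-root test list (so users can apply their own rule)."""
        rows = []
        for ct in self.clade_tests:
            rows.append(
                {
                    "clade": ct.label,
                    "a": ct.a,
                    "b": ct.b,
                    "bootstrap": ct.bootstrap,
                    "posterior": ct.posterior,
                    "intra_dist": ct.intra_dist,
                    "intra_inter": ct.intra_inter_ratio,
                    "av_ma": ct.av_ma,
                    "pab": ct.pab,
                    "prd": ct.prd.p if ct.prd else None,
                    "pid_strict": ct.pid_strict.p if ct.pid_strict else None,
                    "pid_liberal": ct.pid_liberal.p if ct.pid_liberal else None,
                    "significant": ct.significant,
                    "members": ";".join(sorted(ct.clade)),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 1: predefinition
# ---------------------------------------------------------------------------


def predefine_motus(tree, network, accession_to_haplotype, config):
    """Maximal supported, network-independent clades (candidate MOTUs).

    Tips without a haplotype mapping (accessions excluded from the
    network analysis, e.g. for missing data) are ignored by the
    network-independence condition; a clade with no mapped tip at all is
    an error.
    """
    comp_of = network.component_of()
    comp_accessions = {}
    for i, comp in enumerate(network.components):
        accs = set()
        for hap in comp:
            accs |= {
                acc
                for acc, h in accession_to_haplotype.items()
                if h == hap
            }
        comp_accessions[i] = accs

    mapped_tips = set(accession_to_haplotype)

    def independent(clade):
        mapped = clade & mapped_tips
        if not mapped:
            return None
        comps = {comp_of[accession_to_haplotype[t]] for t in mapped}
        if len(comps) != 1:
            return None
        (ci,) = comps
        if comp_accessions[ci] - clade:
            return None  # component shared with non-members
        return ci

    candidates = []

    def visit(node):
        clade = PhyloTree.clade_tips(node) if not node.is_leaf() else frozenset(
            [node.taxon.label]
        )
        # the root is candidate-eligible regardless of support: when the whole
        # ingroup is one network component, the null outcome is a single MOTU
        eligible = config.support_ok(node) or node.parent_node is None
        ci = independent(clade) if eligible else None
        if ci is not None:
            bs, pp = get_support(node)
            haps = {
                accession_to_haplotype[t]
                for t in clade & mapped_tips
            }
            candidates.append(
                Candidate(
                    tips=clade,
                    component=f"C{ci + 1}",
                    n_haplotypes=len(haps),
                    bootstrap=bs,
                    posterior=pp,
                    testable=len(haps) > 1,
                )
            )
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.tree.seed_node)

    # isolated single haplotypes not absorbed by any candidate: report as
    # untestable candidates when their accessions form a clade (or one tip)
    covered = set()
    for cand in candidates:
        covered |= cand.tips
    tips = tree.tip_set()
    for i, comp in enumerate(network.components):
        if len(comp) != 1:
            continue
        accs = frozenset(comp_accessions[i]) & tips
        if not accs or accs & covered:
            continue
        try:
            node = tree.mrca(accs)
        except TreeError:
            continue
        clade = (
            frozenset([node.taxon.label])
            if node.is_leaf()
            else PhyloTree.clade_tips(node)
        )
        if clade != accs:
            continue
        bs, pp = get_support(node)
        candidates.append(
            Candidate(
                tips=accs,
                component=f"C{i + 1}",
                n_haplotypes=1,
                bootstrap=bs,
                posterior=pp,
                testable=False,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Stage 2: tip-to-root clade testing
# ---------------------------------------------------------------------------


def _clade_labels(tree):
    """Paper-style depth-indexed labels for internal non-root nodes."""
    labels = {}
    counters = {}
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        depth = 0
        nd = node
        while nd.parent_node is not None:
            depth += 1
            nd = nd.parent_node
        counters[depth] = counters.get(depth, 0) + 1
        labels[node] = f"{depth}-{counters[depth]}"
    return labels


def tip_to_root(tree, config, null_R=None):
    """Test every >= 2-tip clade against its sister, tips toward root."""
    if len(tree.tree.seed_node.child_nodes()) < 2:
        raise TreeError("tip-to-root testing requires a rooted tree")
    tree._require_lengths()
    if null_R is None:
        rng = np.random.default_rng(config.seed)
        null_R = simulate_null_R(len(tree), config.prd_reps, rng)
    labels = _clade_labels(tree)
    tests = []
    for node in tree.tree.postorder_internal_node_iter():
        if node.parent_node is None:
            continue
        clade = PhyloTree.clade_tips(node)
        if len(clade) < 2:
            continue
        tests.append(
            clade_test(
                tree,
                clade,
                label=labels[node],
                prd_reps=config.prd_reps,
                pid_resamples=config.pid_resamples,
                seed=config.seed,
                null_R=null_R,
                pab_threshold=config.pab_threshold,
                prd_threshold=config.prd_threshold,
                compute_pid=config.compute_pid,
            )
        )
    return tests


# ---------------------------------------------------------------------------
# Acceptance
# ---------------------------------------------------------------------------


def _accept(tree, candidates, tests, config):
    by_clade = {t.clade: t for t in tests}
    node_support_ok = {}
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is not None:
            node_support_ok[PhyloTree.clade_tips(node)] = config.support_ok(node)

    motus = []
    untested = []
    for cand in candidates:
        if not cand.testable:
            untested.append(cand)
            continue
        # significant, supported clades strictly nested in this candidate
        nested = [
            t
            for t in tests
            if t.clade < cand.tips
            and t.significant
            and node_support_ok.get(t.clade, False)
        ]
        # finest: keep only clades containing no other selected clade
        finest = [
            t
            for t in nested
            if not any(o.clade < t.clade for o in nested)
        ]
        # drop overlaps deterministically (clades are nested or disjoint on
        # a tree, so finest clades are pairwise disjoint by construction)
        if not finest:
            motus.append(
                MOTU(
                    motu_id="",
                    tips=cand.tips,
                    source="predefined",
                    component=cand.component,
                    clade_test=by_clade.get(cand.tips),
                )
            )
            continue
        used = set()
        for t in sorted(finest, key=lambda t: sorted(t.clade)[0]):
            motus.append(
                MOTU(
                    motu_id="",
                    tips=t.clade,
                    source="tip-to-root",
                    component=cand.component,
                    clade_test=t,
                )
            )
            used |= t.clade
        residual = cand.tips - used
        if residual:
            motus.append(
                MOTU(
                    motu_id="",
                    tips=frozenset(residual),
                    source="residual",
                    component=cand.component,
                    clade_test=by_clade.get(frozenset(residual)),
                )
            )
    for i, m in enumerate(motus):
        m.motu_id = f"MOTU{i + 1}"
    assigned = set().union(*[m.tips for m in motus]) if motus else set()
    for c in untested:
        assigned |= c.tips
    unassigned = sorted(tree.tip_set() - assigned)
    return MOTUPartition(motus=motus, untested=untested, unassigned=unassigned)


def delimit(tree, alignment, config=DelimitationConfig()):
    """Run the full two-stage delimitation; returns a DelimitationResult."""
    if config.outgroup:
        tree = tree.prune_tips(config.outgroup)
        alignment = alignment.subset_rows(
            set(alignment.ids) - set(config.outgroup)
        )
    missing = tree.tip_set() - set(alignment.ids)
    if missing:
        raise TreeError(f"tree tips missing from alignment: {sorted(missing)[:5]}")
    alignment = alignment.subset_rows(tree.tip_set())

    table = haplotypes.collapse(alignment, config.collapse_policy)
    if config.connection_limit is not None:
        limit = config.connection_limit
    else:
        limit = parsnet.connection_limit(table.n_retained_sites, config.alpha)
    network = parsnet.build_network(table, limit, alpha=config.alpha)
    acc2hap = table.accession_to_haplotype()

    candidates = predefine_motus(tree, network, acc2hap, config)
    rng = np.random.default_rng(config.seed)
    null_R = simulate_null_R(len(tree), config.prd_reps, rng)
    tests = tip_to_root(tree, config, null_R=null_R)
    partition = _accept(tree, candidates, tests, config)
    return DelimitationResult(
        partition=partition,
        candidates=candidates,
        clade_tests=tests,
        network=network,
        haplotype_table=table,
        config=config,
    )
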
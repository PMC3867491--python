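"""Statistical-parsimony network analysis (SPNA).

The parsimony criterion asks: if two haplotypes differ at ``j`` of ``L``
sites, what is the probability that their mutational connection is
*non-homoplasious*, i.e. that no site was hit by more than one
substitution?  Haplotype pairs are connected only while that probability
stays at or above the confidence level (0.95 by default); the largest
acceptable ``j`` is the *connection limit*.

The probability is computed under a finite-sites Jukes-Cantor model.
Conditional on a pairwise divergence of ``t`` expected substitutions per
site, the number of hits at a site is Poisson(``t``), so

* P(j observed differences and no multiply-hit site | t)
  = C(L,j) (t e^-t)^j (e^-t)^(L-j)
* P(j observed differences | t) = C(L,j) p(t)^j (1-p(t))^(L-j),
  with p(t) = 3/4 (1 - e^(-4t/3)) the JC mismatch probability.

The divergence is unknown, so both quantities are averaged over a
uniform prior t in (0, T]; their ratio is the parsimony probability.
T defaults to 1.5 (far beyond saturation for the loci this pipeline
targets).  :func:`mc_parsimony_probabilities` estimates the same
conditional probability by direct simulation of per-site Poisson hit
counts and serves as an independent check of the closed-form route.

Networks are built Kruskal-style on the haplotype step matrix: edges in
non-decreasing step order (ties broken lexicographically by haplotype
id) are added when they join two distinct components, or retained as
loops when they tie the step count at which their endpoints' components
were joined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammainc, gammaln

from .haplotypes import haplotype_distance_matrix

__all__ = [
    "ParsimonyNetwork",
    "parsimony_probability",
    "connection_limit",
    "mc_parsimony_probabilities",
    "mc_connection_limit",
    "build_network",
    "components",
]

DEFAULT_T_MAX = 1.5


def _jc_mismatch(t):
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def parsimony_probability(j, L, t_max=DEFAULT_T_MAX):
    """Probability that a j-step difference over L sites is non-homoplasious.

    Decreasing in j at fixed L; 1.0 for identical haplotypes.
    """
    if j < 0 or int(j) != j:
        raise ValueError("j must be a non-negative integer")
    if L < 1:
        raise ValueError("L must be >= 1")
    j = int(j)
    if j > L:
        raise ValueError(f"j={j} exceeds L={L}")
    if j == 0:
        return 1.0

    # numerator: integral of t^j e^{-Lt} dt over (0, T]  (binomials cancel)
    log_num = gammaln(j + 1) - (j + 1) * math.log(L)
    num = math.exp(log_num) * float(gammainc(j + 1, L * t_max))

    # denominator: integral of p(t)^j (1-p(t))^(L-j) dt.  The integrand is
    # unimodal with mode at p(t*) = j/L and width ~ sqrt(j)/L in t, far too
    # sharp for blind quadrature at large L, so integrate on a grid dense
    # around the mode (Laplace width) plus a coarse global grid.
    frac = min(j / L, 0.7499)
    t_star = -0.75 * math.log1p(-(4.0 / 3.0) * frac)
    dp_dt = math.exp(-4.0 * t_star / 3.0)
    sigma = max(1e-9, math.sqrt(max(j, 1)) / (L * dp_dt))
    local = np.linspace(max(0.0, t_star - 10 * sigma),
                        min(t_max, t_star + 10 * sigma), 600)
    coarse = np.linspace(0.0, t_max, 400)
    grid = np.unique(np.concatenate([local, coarse]))
    p = _jc_mismatch(grid)
    with np.errstate(divide="ignore"):
        log_f = j * np.log(p) + (L - j) * np.log1p(-p)
    log_f[p <= 0.0] = -np.inf
    peak = np.max(log_f)
    if not np.isfinite(peak):
        return 0.0
    den = math.exp(peak) * float(np.trapezoid(np.exp(log_f - peak), grid))
    if den <= 0.0:
        return 0.0
    return min(1.0, num / den)


def connection_limit(L, alpha=0.95, t_max=DEFAULT_T_MAX):
    """Largest j with parsimony_probability(j, L) >= alpha."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    limit = 0
    for j in range(1, L + 1):
        if parsimony_probability(j, L, t_max=t_max) >= alpha:
            limit = j
        else:
            break
    return limit


def _default_t_grid(L, t_max):
    # fine spacing where small-j pairs live, coarse towards saturation
    fine_hi = min(t_max, max(0.05, 80.0 / L))
    fine = np.linspace(1e-4, fine_hi, 60)
    coarse = np.linspace(fine_hi, t_max, 40)[1:]
    return np.concatenate([fine, coarse])


def mc_parsimony_probabilities(
    L,
    j_max,
    t_max=DEFAULT_T_MAX,
    pairs_per_t=2000,
    t_grid=None,
    seed=0,
):
    """Monte-Carlo estimate of the parsimony probability for j = 1..j_max.

    Simulates pairs of sequences under finite-sites Jukes-Cantor across a
    grid of divergences (trapezoid-weighted uniform prior): per-site hit
    counts are Poisson, a site hit k times mismatches with probability
    3/4 (1 - (-1/3)^k), and a pair is parsimonious when no site is hit
    more than once.  Returns (p_hat, n_eff) arrays indexed by j (index 0
    unused).
    """
    rng = np.random.default_rng(seed)
    if t_grid is None:
        t_grid = _default_t_grid(L, t_max)
    weights = np.gradient(t_grid)
    tot = np.zeros(j_max + 1)
    par = np.zeros(j_max + 1)
    counts = np.zeros(j_max + 1)
    for t, w in zip(t_grid, weights):
        hits = rng.poisson(t, size=(pairs_per_t, L))
        p_diff = 0.75 * (1.0 - (-1.0 / 3.0) ** hits)
        diff = rng.random((pairs_per_t, L)) < p_diff
        j_obs = diff.sum(axis=1)
        pars = ~(hits >= 2).any(axis=1)
        sel = j_obs <= j_max
        jo = j_obs[sel]
        np.add.at(tot, jo, w)
        np.add.at(par, jo, w * pars[sel])
        np.add.at(counts, jo, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(tot > 0, par / tot, np.nan)
    return p_hat, counts


def mc_connection_limit(L, alpha=0.95, t_max=DEFAULT_T_MAX, seed=0, **kw):
    """Connection limit estimated from the Monte-Carlo route."""
    j_max = max(5, int(3 * math.sqrt(L)))
    p_hat, counts = mc_parsimony_probabilities(
        L, j_max, t_max=t_max, seed=seed, **kw
    )
    limit = 0
    for j in range(1, j_max + 1):
        if counts[j] < 50 or np.isnan(p_hat[j]):
            break
        if p_hat[j] >= alpha:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass
class ParsimonyNetwork:
    """Haplotype graph under a connection limit.

    ``graph`` is an undirected networkx graph whose nodes are haplotype
    ids (with a ``frequency`` attribute) and whose edges carry ``steps``;
    ``components`` is the induced partition of haplotype ids.
    """

    graph: nx.Graph
    alpha: float
    connection_limit: int
    components: list = field(default_factory=list)

    def component_of(self):
        return {h: i for i, comp in enumerate(self.components) for h in comp}

    @property
    def n_networks(self):
        """Components with more than one haplotype ("independent networks")."""
        return sum(1 for c in self.components if len(c) > 1)

    @property
    def n_singletons(self):
        return sum(1 for c in self.components if len(c) == 1)


def build_network(table, limit, alpha=0.95, distance_matrix=None):
    """Connect haplotypes whose step distance is within the limit.

    Edges are considered in non-decreasing step order with a
    lexicographic tie-break on haplotype ids.  Within one step value, an
    edge is added when its endpoints lie in different components as of
    the start of that step value; equal-step alternative connections
    between already-joined components are retained as loops.
    """
    if limit < 0:
        raise ValueError("limit must be >= 0")
    ids = [h.hap_id for h in table.haplotypes]
    if distance_matrix is None:
        distance_matrix = haplotype_distance_matrix(table)
    g = nx.Graph()
    for h in table.haplotypes:
        g.add_node(h.hap_id, frequency=h.frequency)

    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            steps = int(distance_matrix[i, j])
            if steps <= limit:
                a, b = sorted((ids[i], ids[j]))
                edges.append((steps, a, b))
    edges.sort()

    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = 0
    while k < len(edges):
        step_val = edges[k][0]
        group = []
        while k < len(edges) and edges[k][0] == step_val:
            group.append(edges[k])
            k += 1
        comp_before = {h: find(h) for h in ids}
        for steps, a, b in group:
            if comp_before[a] != comp_before[b]:
                g.add_edge(a, b, steps=steps)
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return ParsimonyNetwork(
        graph=g, alpha=alpha, connection_limit=int(limit), components=comps
    )


def components(network):
    """Partition of haplotype ids with per-component summaries.

    Returns a list of dicts: haplotype ids, haplotype count, total
    accession frequency, and a singleton flag ("isolated single
    haplotype").
    """
    out = []
    for comp in network.components:
        freq = sum(network.graph.nodes[h].get("frequency", 1) for h in comp)
        out.append(
            {
                "haplotypes": list(comp),
                "n_haplotypes": len(comp),
                "n_accessions": freq,
                "singleton": len(comp) == 1,
            }
        )
    return out
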
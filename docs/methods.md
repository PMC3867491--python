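# Methods

This note documents the models behind `motudelim`, the choices made
where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## Reciprocal monophyly: P(AB)

`rosenberg_pab(a, b)` is the probability that two groups of sizes `a`
and `b` are reciprocally monophyletic on a random genealogy.  The
default null takes every *coalescent labeled history* as equiprobable,
giving the closed form `2 a! b! (n−2)! / (n! (n−1)!)` with `n = a + b`.
The implementation uses exact rational arithmetic (`fractions`), so it
is overflow-safe for group sizes in the hundreds and agrees to the last
digit with `pab_enumerated`, an independent recursion over the merge
process (itself validated in the test suite against literal enumeration
of every labeled history for n ≤ 6).  A uniform-labeled-topology null
(`null="topologies"`, probability `(2a−3)!! (2b−3)!! / (2n−3)!!`) is
available for sensitivity analysis; the coalescent null is the default
because the distinctiveness framework is explicitly coalescent-based.

Caveat: applied tip-to-root, the tested groups are clades *of the
estimated tree*, so reciprocal monophyly is observed by construction
and P(AB) is mechanically small for large balanced splits (a (10,10)
split gives 5.7 × 10⁻⁷ on any tree).  This is why the acceptance rule
gates nested splits on clade support as well as on the statistic (see
"Delimitation rule" below).

## Randomly distinct clades: P(RD)

The distinctness statistic for a clade is `R = Av(MA) / (Av(MA) + s)`,
where `Av(MA)` is the mean MRCA-to-member path length and `s` the
length of the branch subtending the clade.  `R → 0` for a shallow clade
on a long stem (maximally distinct), `R → 1` for a clade whose stem is
negligible.  R is scale-free, so only tree *shape* matters under the
null and the null tree height needs no calibration: on an ultrametric
coalescent tree R reduces to the ratio of a node's height to its
parent's height, which is how the null is simulated.

The null distribution pools R over all internal non-root clades of
`reps` Kingman coalescent genealogies with the same total tip count as
the analysed tree; `P(RD)` is the fraction of null values ≤ the
observed R, and the result carries its Monte-Carlo standard error,
replicate count and seed.  Within one delimitation run the null pool is
simulated once and shared by all clades.  Self-calibration (a clade
drawn at random from a null tree, ranked against a fresh null pool) is
uniform to within Monte-Carlo error; the acceptance suite checks that
the fraction below 0.05 is 0.05 ± 0.02 over 500 trials.

The exact constants of the original plugin implementation are not
recoverable from the source study; the Monte-Carlo definition above is
normative for this package.

## P ID (strict / liberal)

Operationalised as leave-one-out nearest-neighbour placement: a member
is correctly identified under *strict* if its nearest non-self tip by
patristic distance lies inside the group, under *liberal* if inside the
group or the sister of the group's spanning clade.  Ties count as
correct.  The point estimate is the mean over members; the 95% CI is a
seeded nonparametric bootstrap over members (percentile method, clipped
to bracket the point estimate).  Groups need not be monophyletic —
identification of a possibly non-exclusive set is what the measure
probes — and singletons are returned explicitly as untestable rather
than as a number.  This is a deliberate re-operationalisation: the
regression approximation used by the original plugin is not published,
while the verbal definition ("found only in the group of interest" /
"sister to or within the group") maps directly onto nearest-neighbour
placement.

## Statistical parsimony and the connection limit

Two haplotypes differing at `j` of `L` sites are connected
*parsimoniously* when no site on the path between them was hit more
than once.  Conditional on a pairwise divergence `t` (expected
substitutions/site), per-site hit counts are Poisson(`t`), so

    P(j observed, parsimonious | t) = C(L,j) (t e^(−t))^j (e^(−t))^(L−j)
    P(j observed | t)               = C(L,j) p(t)^j (1 − p(t))^(L−j)

with `p(t) = ¾(1 − e^(−4t/3))` the Jukes–Cantor mismatch probability.
The parsimony probability is the ratio of the two after averaging over
a uniform prior on `t ∈ (0, 1.5]` (1.5 is saturation-level divergence
for these markers; results are insensitive to the cap because the
posterior mass given small `j/L` sits near `t ≈ j/L`).  The numerator
integrates in closed form (incomplete gamma); the denominator is
integrated on a grid densified around its mode `p(t*) = j/L` with
Laplace width `√j / L`, since the integrand is far too sharp at large
`L` for blind quadrature.  `connection_limit(L, α)` is the largest `j`
whose probability stays ≥ α; identical haplotypes have probability 1
by definition.

`mc_parsimony_probabilities` estimates the same conditional probability
by direct simulation — per-site Poisson hit counts, mismatch given `k`
hits with probability `¾(1 − (−⅓)^k)`, trapezoid weights over the same
divergence prior — and serves as an independent check; the shipped
closed form agrees with it within ±1 step on the 95% limit at
L ∈ {200, 400, 1000, 1500} (acceptance suite).  At α = 0.95 the limit
is 5 steps for a 402-site matrix and 11 steps for 1464 sites.

Networks are built Kruskal-style on the haplotype step matrix: edges in
non-decreasing step order (lexicographic tie-break on haplotype ids),
added when they join components distinct as of the start of that step
value; equal-step alternative connections are retained as loops but do
not affect the component partition.  Hypothetical unsampled
intermediate haplotypes (median vectors) are *not* materialised:
the pipeline consumes networks only through component membership and
counts, so inserting inferred intermediates would change nothing
downstream while complicating the graph; this is a documented deviation
from full TCS behaviour.

## Haplotype collapsing

Accessions share a haplotype when they agree at every retained column.
Defaults mirror standard pre-network practice: columns containing a gap
are dropped, accessions containing '?' are dropped (and reported), and
IUPAC ambiguity codes are non-discriminating ("missing"), with
first-occurrence greedy assignment and representative sequences that
accumulate their members' definite states (the compatibility relation
is not transitive, so some deterministic order rule is unavoidable).
When gap columns are retained, '-' acts as a definite fifth state.
Haplotypes are numbered H1..Hk by first occurrence, making the collapse
reproducible for a given input order.

## Two-stage delimitation

Stage 1 — *predefinition*: candidates are the maximal clades that meet
the support condition (bootstrap ≥ 95 or posterior ≥ 0.95 by default;
AND and ignore modes available) and whose members' haplotypes form
exactly one network component shared with no outside accession.  The
root is candidate-eligible regardless of support so that a structureless
sample degrades to "one unit" rather than to nothing.  Accessions
excluded from the network (missing data) are ignored by the
independence check rather than poisoning their clade.  Isolated single
haplotypes outside every candidate are reported as untested candidates.

Stage 2 — *tip-to-root*: every clade with ≥ 2 tips is tested against
its sister group (post-order, tips toward root), labelled
`<depth>-<index>`, and scored with all statistics above.

Acceptance: a testable candidate stands as one MOTU unless it strictly
contains clades that pass *both* the support condition *and* the
distinctiveness rule (`P(AB) < 10⁻⁵` or `P(RD) ≤ 0.05`); then the
finest such clades replace it and the residual members (if any) form a
sibling MOTU.  Requiring support for nested splits is deliberate:
tree-defined splits make P(AB) anti-conservative (see above), and
unsupported splits are exactly the ones whose monophyly is not
trustworthy in the first place.  Single-haplotype candidates are
reported as untested units, never silently merged.  The raw clade-test
table is always emitted so users can apply alternative rules.

## Synthetic data

The generator produces a Yule species tree (waiting times Exp(i·λ);
expected root height Σᵢ 1/(iλ)), multispecies-coalescent gene trees
(Kingman within branches, survivors merged at speciation nodes;
cross-checked against msprime in the test suite), and finite-sites
JC69/HKY85 sequences, all in expected-substitutions/site units so
simulated trees feed the patristic machinery directly.

Defaults emulate a two-locus study of a liverwort species complex:
loci of 402 and 1062 bp, 8–23 accessions per species, and
Ne = 0.0005 substitutions/site — intraspecific pairwise diversity
around 0.001 (≈ 1–3 observed steps between haplotypes), which keeps
within-species variation safely inside the 95% connection limit while
still making species polymorphic, the regime the empirical study sits
in.  The `deep4` preset rescales the species tree so the shallowest
split equals 20 Ne; both loci share one gene tree by default
(mirroring a combined-data analysis of linked evidence;
`linked_loci=False` gives independent genealogies per locus for
conflict-detection tests).

Support values are not inferred (tree inference is outside this
package's scope); instead the generator annotates gene-tree clades that
are unions of complete species samples with bootstrap 100 / posterior
1.0 and leaves intraspecific nodes unannotated.  This emulates the
empirical pattern that species-level clades attract maximal support
while shallow intraspecific nodes lack it.  Consequently the synthetic
experiments exercise the network-independence and statistical stages
fully, but the support *thresholds* themselves are only exercised by
unit tests with hand-annotated trees; passing synthetic tests says
nothing about the behaviour of real bootstrap values near the 95% cut,
nor about alignment error, rate variation among lineages, gaps or
sequencing artefacts, none of which the generator produces.

## Experiment scales and scoring

The validation experiments (`motudelim.validation`, also run by
`scripts/acceptance.py`) use: 500 calibration trials at 20 tips with
200-tree null pools; 100 single-species replicates and 50 four-species
replicates at 200 null trees per run; Monte-Carlo connection-limit
checks with ~1500 simulated pairs per divergence grid point.  These
sizes put Monte-Carlo error comfortably below each decision margin
while keeping a full run in minutes on one CPU.

Recovery is scored on *delimited units* — accepted MOTUs plus untested
single-haplotype candidates — against the true species partition.  A
simulated species that happens to be monomorphic is returned as an
untested candidate with exactly the right members; that is correct
delimitation behaviour (single-haplotype units are by definition
untestable with these statistics), not an error, so it counts as
recovery.  Fragmentation of a species across several network
components, spurious splits and merged species all count as failures.

## Known limitations

- P(AB) and P(RD) applied to tree-defined clades are not independent
  tests of those clades; the support gate mitigates but does not remove
  the circularity.
- The connection-limit calculation is a principled finite-sites
  reconstruction, not a re-implementation of the historical TCS
  recursion; limits may differ from TCS by a step or two on real data.
- The coalescent null for P(RD) assumes a single panmictic population
  with no population growth or structure.
- The generator does not simulate alignment ambiguity, indel evolution,
  introgression or hybridisation; conclusions about those regimes are
  out of reach of the shipped experiments.
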
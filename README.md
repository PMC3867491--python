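# motudelim

Coalescent species delimitation from DNA sequence variation.

`motudelim` implements, as a tested and reusable pipeline, the
delimitation workflow used in single- and few-locus studies of cryptic
species complexes (the motivating setting is a two-locus — plastid
*trnL–F* plus nuclear ITS — survey of a morphologically conserved
liverwort species complex): collapse aligned accessions into
haplotypes, build statistical-parsimony networks at a 95% connection
limit, score every clade of a rooted phylogram with coalescent
distinctiveness statistics, and partition the sample into molecular
operational taxonomic units (MOTUs) in two stages — network/support
predefinition followed by iterative tip-to-root sister-clade testing.
A multispecies-coalescent synthetic-data generator makes the whole
pipeline testable end to end without any external download.

## The statistics

For a clade of size *a* with sister group of size *b* (*n = a + b*):

- **Rosenberg's P(AB)** — the probability that two groups of sizes
  *a* and *b* are reciprocally monophyletic on a random coalescent
  genealogy (equiprobable labeled histories):
  `P(AB) = 2 a! b! (n−2)! / (n! (n−1)!)`.
  Evaluated in exact rational arithmetic and verified against
  brute-force enumeration of labeled histories.
- **Rodrigo's P(RD)** — "randomly distinct": with `Av(MA)` the mean
  path length from the clade's MRCA to its members and *s* the length
  of its stem branch, the statistic `R = Av(MA) / (Av(MA) + s)` is
  scale-free; P(RD) is the fraction of clades on simulated Kingman
  coalescent trees (same tip count) whose R is at most the observed R.
- **P ID (strict / liberal)** — leave-one-out probability that a
  member's nearest tip by patristic distance falls inside the group
  (strict) or inside the group or its sister (liberal), with a
  bootstrap 95% CI over members.
- **Connection limit** — the largest number of mutational steps *j*
  between haplotypes of an *L*-site matrix such that the probability of
  a non-homoplasious (parsimonious) connection stays ≥ 95%, computed
  under a finite-sites Jukes–Cantor model and cross-checked against a
  Monte-Carlo simulation of per-site substitution hits.

A clade is flagged genetically distinct when `P(AB) < 10⁻⁵` or
`P(RD) ≤ 0.05`.  Accepted MOTUs are the maximal supported,
network-independent clades, refined by nested supported clades that
pass the distinctiveness rule (with residual members forming a sibling
MOTU); single-haplotype candidates are reported as untested.

## Worked example

Simulate four species (8–23 accessions each, loci of 402 + 1062 bp,
species splits at 20 Ne) and delimit them:

```
$ motudelim simulate --preset deep4 --seed 5 --out demo
demo/: 53 accessions x 1464 bp, 4 true species

$ motudelim delimit --tree demo/analysis_tree.nwk \
    --alignment demo/alignment.fasta --prd-reps 1000 --seed 5 --out demo/delim
4 MOTUs (0 untested single-haplotype candidates, 0 unassigned tips)
```

`demo/delim.summary.json` records 17 haplotypes joined into 4
independent networks at a connection limit of 11 steps, and
`demo/delim.evidence.tsv` holds the per-MOTU evidence table:

```
 motu  n_tips network_component          pab      prd  pid_strict  significant
MOTU1       8                C1 8.450880e-09 0.062941         1.0         True
MOTU2      23                C4 8.450880e-09 0.200098         1.0         True
MOTU3      14                C2 2.723928e-13 0.002745         1.0         True
MOTU4       8                C3 4.339451e-11 0.001020         1.0         True
```

Each row is one accepted MOTU: all four coincide with a single
parsimony network (`network_component`), their reciprocal monophyly
would be essentially impossible under a random coalescent
(`pab` ≪ 10⁻⁵, hence `significant`), and every leave-one-out query is
placed correctly (`pid_strict = 1.0`).  The `prd` column shows why the
joint rule matters: a deep but internally diverse clade (MOTU2) is not
"randomly distinct" by R alone yet is unambiguous by P(AB).
`demo/delim.clades.tsv` lists every tip-to-root sister-clade test with
its depth-indexed label so alternative acceptance rules can be applied
downstream.

The same machinery is available as a library:

```python
from motudelim import delimit, generate_dataset, preset, DelimitationConfig

ds = generate_dataset(preset("deep4", seed=5))
res = delimit(ds.analysis_tree, ds.alignment, DelimitationConfig(seed=5))
print(res.partition.n_motus)            # 4
print(res.report())                     # evidence table as a DataFrame
```

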
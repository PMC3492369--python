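# ctdnet

Local-network-topology scoring and ranking of transitive chemical–disease
inferences in tripartite chemical–gene–disease association networks, in the
style of the Comparative Toxicogenomics Database (CTD) network score.

## The problem

Curated toxicogenomics databases record three kinds of direct, literature-
curated associations: chemical–gene interactions, gene–disease
relationships and chemical–disease relationships.  Combining the first two
transitively yields *inferred* chemical–disease relationships: chemical *X*
is linked to disease *Y* whenever one or more genes (the connector set *A*,
of size *m*) interact with both.  The number of such inferences grows
explosively with curation depth, and because these networks are scale-free,
hub nodes (heavily studied chemicals, genes and diseases) generate large
numbers of overlaps by connectivity alone.  Ranking inferences therefore
requires statistics that reward many shared genes while discounting hubs.

`ctdnet` implements that scoring system for anyone who wants to rank
transitive inferences in their own association data or study the behavior
of the statistics themselves: the five local-topology statistics, Bonferroni
correction, a degree-preserving shuffle null model, ranking/tie/classifier
diagnostics, and a seeded synthetic-network generator so everything runs
and is testable without any database download.

## The statistics

For an inference between chemical *x* (degree *n_x*) and disease *y*
(degree *n_y*) through *m* genes with degrees *n_i*, inside a network of
*N* connected nodes:

- **C_xy** — hypergeometric mutual clustering coefficient: the upper-tail
  probability of observing ≥ *m* common neighbors,
  `C_xy = −log10 Σ_{i=m}^{min(n_x,n_y)} C(n_x,i) C(N−n_x, n_y−i) / C(N, n_y)`.
- **p1** — the point probability of exactly the observed overlap, the
  hypergeometric mass at *m*, reported on the natural-log scale
  (`p1 = −ln [C(n_x,m) C(N−n_x, n_y−m) / C(N, n_y)]`; see
  `docs/methods.md` on the score system's mixed logarithm bases).
- **p2** — connector-degree statistic,
  `p2 = Σ_{i∈A} log10 [N(N−1) / (n_i(n_i−1))]`: low-degree connecting
  genes are surprising, hub genes are not.
- **S_XYA** — equal-weight logarithmic opinion pool, `(p1 + p2) / 2`.
- **W_XYA** — *m*-weighted pool `w1(m)·p1 + w2(m)·p2`, where the weight
  shifts onto p1 geometrically as the gene set grows, so hub diseases
  inferred through hundreds of genes do not dominate purely through the
  additive p2 term.

All probability work is done in log space (log-gamma binomials,
log-sum-exp tails), so degrees in the thousands against *N* ~ 10⁴–10⁵ are
exact to machine precision.

## Worked example

`examples/worked_example_scores.py` scores the two classic nine-gene
inferences against Breast Neoplasms from their published degrees:

```
malathion: chemical degree 54, disease degree 443, m=9
  gene-degree geometric mean = 125.8
  C_xy = 8.00   p1 = 18.47   p2 = 44.88
  S_XYA = 31.68   W_XYA = 18.48
pioglitazone: chemical degree 60, disease degree 443, m=9
  gene-degree geometric mean = 383.7
  C_xy = 7.58   p1 = 17.52   p2 = 36.13
  S_XYA = 26.82   W_XYA = 17.52
```

Both inferences run through nine genes and nearly identical endpoint
degrees, so C_xy and p1 barely separate them.  The malathion gene set is
three times less connected (geometric mean degree 125.8 vs 383.7), which
p2 rewards — and the pooled statistics rank the malathion inference
higher, exactly the hub discounting the score system was designed for.
(Absolute values depend on the configured network size N; here the
calibrated snapshot N = 38,930 carried by the fixture.)

Other capabilities, one script each under `examples/`:

- `simulate_score_rank.py` — synthetic network → enumerate → score → rank.
- `shuffle_null_comparison.py` — real vs degree-preserving shuffle.
- `ties_and_classifier.py` — tie diagnostics and the median-threshold
  classifier.

A thin CLI wraps the same library calls:

```sh
ctdnet simulate --seed 1 --out-dir net/
ctdnet score --chem-gene net/chem_gene.tsv --gene-disease net/gene_disease.tsv \
             --chem-disease net/chem_disease.tsv --out run/
ctdnet rank --scores run/scores.tsv --score w_xya --out ranked.tsv
ctdnet shuffle --chem-gene net/chem_gene.tsv --gene-disease net/gene_disease.tsv \
               --chem-disease net/chem_disease.tsv --swaps 100000 --seed 7
```

Input tables are two-column TSV pair lists (`#` comments, optional gzip) or
named-column exports (`--dialect ctd_export`).

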
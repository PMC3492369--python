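# Methods

## Network model

Associations are modeled as a binary tripartite graph: chemicals, genes and
diseases as nodes; curated chemical–gene, gene–disease and chemical–disease
associations as undirected, unweighted edges confined to those three
layers.  Multiple curated reports of the same pair collapse to one edge.
A node's degree is its edge count pooled over all layers it participates
in (a chemical accrues degree from both the chemical–gene and
chemical–disease layers); *N* is the number of nodes with at least one
edge.  Everything downstream — the hypergeometric statistics, the shuffle
null, the generator — operates on this model.

*N* is deliberately a configuration value rather than something the
statistics read off the loaded network silently: scores published for a
given database snapshot are reproducible only with that snapshot's
effective *N*, and entity counts quoted for a release do not reliably
equal it.  The worked-example fixtures carry a calibrated snapshot value
of N = 38,930, which reproduces the published example rows to their
printed precision (see "Score scales" below); `score_table` and the CLI
accept an override, and default to the loaded network's own *N*.

## The five statistics

Let *x* be the chemical with degree `n_x`, *y* the disease with degree
`n_y`, *A* the set of `m` connecting genes with degrees `n_i`, and *N* the
connected-node count.

**C_xy** (hypergeometric mutual clustering coefficient).  Under the null
that *y*'s `n_y` neighbors are drawn uniformly from the *N* nodes,
independent of *x*'s `n_x` neighbors, the chance of sharing at least *m*
of them is the hypergeometric upper tail; `C_xy` is its −log10.  The tail
runs from *m* to `min(n_x, n_y)` (larger overlaps are combinatorially
impossible) and overlaps below `n_x + n_y − N` carry zero mass.

**p1** (common-neighbor count statistic).  The point probability of
exactly the observed overlap — the hypergeometric mass at *m* — on the
natural-log scale.  Because a point mass can never exceed the tail that
contains it, `p1 ≥ C_xy` always holds (the log-base difference only widens
the gap).

**p2** (connector-degree statistic).  Each connecting gene independently
"chooses" two endpoints; for a gene of degree `n_i` the chance that two
designated nodes are among them scales as `n_i(n_i−1)/(N(N−1))`.  `p2` is
the −log10 of the product over *A*.  It is additive over disjoint gene
subsets and strictly decreasing in every `n_i`: hub genes contribute
little surprise, rarely-studied genes contribute much.

**S_XYA / W_XYA** (logarithmic opinion pools).  A log opinion pool with
normalization k = 1 multiplies the component probabilities raised to
weights, i.e. adds the log-scale statistics with weights `w1, w2`.  `S`
uses `w1 = w2 = 1/2`.  `W` uses weights that depend on the gene-set size:

    w1(m) = 1 − 0.737 · 2^(−m)
    w2(m) =     0.339 · 2^(−m)

so the pool starts mixed at small *m* and converges geometrically onto
`p1` as gene sets grow.  The motivation: `p2` is a sum over *A*, so for
inferences through very many genes (hub diseases reach *m* in the
hundreds) an equal-weight pool is dominated by sheer gene count; draining
the `p2` weight with *m* keeps such inferences comparable.  The constants
are calibrated so that the weights at m = 5 equal the pair
(w1 = 0.97697, w2 = 0.010594) implied by published example score tables —
two independent published rows pin the weights as a 2×2 linear system, and
the schedule reproduces both published W values to ±0.001, as well as the
published m = 9 worked example to ±0.01.  The geometric decay in *m* is
the package's own modeling choice among schedules consistent with the
published values at m = 5, m = 9 and the large-*m* rows (where W ≈ p1).

**Bonferroni correction.**  On the −log10 scale, multiplying the
probability by the number of tests and capping at 1 becomes
`max(0, W − log10(n_tests))`.  The family size defaults to the number of
inferences scored in the current run and can be overridden; a correction
computed for one database release is meaningless for a differently-sized
family.  The conventional significance threshold −log10(0.05) ≈ 1.301 is
the default in the run configuration; a stricter 2.0 (p = 0.01) is
sometimes used in practice and is configurable — the package takes no
position beyond the default.

### Score scales

The published score system mixes logarithm bases: its `p1` values are
natural-log point probabilities while `C_xy` and `p2` are base-10.  This
package reproduces the published scales exactly — 18 of 18 published
example rows match to ±0.006 under this reading at a single N, and no
single-base reading fits — rather than "correcting" them, because the
weight schedule and every published threshold and worked value are defined
on those scales.  Practical consequence: `p1` and `C_xy` are comparable
only through the `p1 ≥ C_xy` inequality, not unit for unit, and the pooled
statistics are weighted sums across two log bases.  All statistics are
computed in log space end to end (log-gamma binomial coefficients,
log-sum-exp for tails), so no intermediate probability is ever
materialized; values are exact to ~1e-12 relative against big-integer
rational arithmetic for N ≤ 500 and stable far beyond.

## Inference enumeration

Transitive inferences are enumerated per source node: for each chemical,
its gene neighbors are expanded to diseases and grouped, yielding one
inference per (chemical, disease) pair with a non-empty shared gene set.
Peak memory is bounded by one node's two-hop neighborhood, not the
cross product.  Inferences whose endpoint pair also has a direct curated
edge are flagged `curated` but still enumerated and scored — curation is
corroborating evidence, not a filter.  The symmetric gene–disease mode
(chemicals as connectors) is provided; the scoring statistics are
role-agnostic.

## Degree-preserving shuffle null

The null model repeatedly selects two chemical–gene edges (c1–g1, c2–g2)
and exchanges the genes, giving c1–g2 and c2–g1.  Every node's layer
degree is exactly conserved, so the scale-free topology survives while
specific co-association structure decays.  A proposal that would duplicate
an existing edge, or whose two edges share a chemical or a gene, is
rejected and redrawn *without* counting toward the swap budget; counting
only applied swaps makes mixing depth comparable across densities.  The
default budget is 10⁶ applied swaps with three replicates; a stalled run
(no acceptable proposal in 200× the budget) raises rather than silently
under-mixing.  Gene–disease shuffling is available behind a flag for
sensitivity analysis but is not part of the standard procedure.

One property worth knowing: in heavily hub-concentrated layers an
appreciable fraction of hub–hub edges is present in *every*
degree-preserving configuration, so the expected edge overlap between a
network and its shuffle equilibrates well above zero (≈ 0.6 on the default
synthetic network).  This is a property of the degree sequence, not
under-mixing — which is why mixing is asserted through degree invariants
and seed-sensitivity rather than an overlap threshold.

Real-vs-shuffled comparison matches inferences by (chemical, disease)
pair, reports the mean W difference (real − shuffled) per stratum
(curated / novel / total), and applies Welch's unequal-variance t-test on
the matched score lists (a paired-test variant is available; the published
procedure does not specify pairing).  An empty match is reported as
undefined, never as a zero difference.

## Ranking, ties, classifier

Display ranking puts curated rows first, then descending score; residual
ties break by larger *m*, then ascending partner id — the tie-break tail
is a determinism device, not a scientific claim.  Tie diagnostics count,
per chemical, rows whose statistic value recurs; `exact_display` mode
(equality after 2-decimal rounding, the default, matching how ties are
visible in published tables) and a `numeric` mode (|Δ| ≤ 1e-9) are both
provided because the operational definition is ambiguous; display-mode
counts are necessarily ≥ numeric-mode counts.  The median-threshold
classifier flags novel inferences scoring strictly above the curated
median; with strict inequality the curated "sensitivity" is 1/2 by
construction for odd-sized distinct-valued samples and 0 when all curated
scores are equal.  `top_k_curated_overlap` ranks by pure score order
(ignoring the curated-first display rule) and counts curated rows in the
top *k*.

## Synthetic data generator

The generator emulates the gross features of curated tripartite
association data at desk scale: three node classes, a dominant
chemical–gene layer, sparser gene–disease and chemical–disease layers, and
a pooled degree distribution whose unit-bin log-log frequency fit has a
shallow slope (target magnitude 0.8 by default).  Defaults: 500 chemicals,
2,000 genes, 300 diseases; 12,000 / 3,000 / 1,500 edges per layer —
a mean degree near 12, matching the edge-to-node ratio of curated
toxicogenomics snapshots.

Construction is an expected-degree (Chung–Lu-style) sampler: each node
draws a weight from a truncated power law and layer edges are sampled with
probability proportional to the endpoint weights, rejecting duplicates, so
graphs are simple by construction.  Growth-style preferential attachment
was rejected as the mechanism because it cannot produce fitted slopes as
shallow as 0.8 — those arise from the long run of singleton high-degree
bins that an equal-weighted least-squares fit averages in, which requires
a hub tail far heavier than linear attachment yields at these sizes.  For
the same reason the internal weight-law exponent is steeper than the
target slope by a calibrated offset (0.45), and per-node weights are
capped at half the opposite side so a hub cannot saturate its layer.  The
fitted slope is a statistical target: across seeds the default spec fits
−0.89 ± 0.03 and a doubled-size spec −0.92 ± 0.01, within the ±0.2
tolerance the tests assert.

What the generator does **not** emulate: literature and curation bias
(real hubs are hubs because they are studied), interaction types and
directions, gene–organism structure, and correlated layer membership.
Tests passing on synthetic networks therefore demonstrate the statistics'
combinatorial behavior (hub penalties, tie structure, null-model
direction), not biological validity on real curated data.

Planted inferences wire *m* genes from a requested degree stratum (low,
hub or mixed) between a chemical and a disease, plus a direct edge when
curated.  Endpoints come in two modes: `background` attaches to
well-connected existing nodes — used for null-model comparisons, because a
shuffled hub chemical still reaches the disease's untouched gene layer and
the planted pair remains matchable — and `fresh` creates dedicated nodes
whose degrees are determined entirely by the plant, the controlled setting
for comparing gene-degree profiles at exactly matched endpoint degrees.

## Numerical and edge-case conventions

- Scores are floored at 0 (probabilities capped at 1) against negative
  round-off on near-certain events.
- `ScoreInputs` validates rather than clamps: `m ≤ min(n_x, n_y)`, every
  connector degree ≥ 2 (a connector touches both endpoints), `N` above
  every degree.  Violations raise with the inference identity attached.
- `C_xy` admits m = 0 only through the raw tail form (`c_xy_tail`), where
  the empty tail is the certain event.
- Welch's test requires ≥ 2 observations per sample; two zero-variance
  samples with equal means return (t = 0, p = 1), with unequal means they
  raise.
- The power-law fit needs ≥ 3 distinct degrees and drops zero-frequency
  bins before the log transform.
- Full precision is kept internally everywhere; 2-decimal rounding exists
  only in display outputs.  Tests compare with tolerances, never rounded
  values.

## Problem sizes

The test suite and examples run everything at desk scale, chosen so the
full suite completes in well under five minutes on one CPU: synthetic
networks of ~2,800 nodes and 16,500 edges (~20–25k inferences, scored
vectorized in ~0.1 s), shuffle runs of 2×10⁴–10⁵ applied swaps, ten-seed
replications for the stochastic claims, and exact rational oracles up to
N = 500.  The statistics themselves are routinely exercised at the
published scale (N ≈ 3.9×10⁴, degrees to 1,247) through the worked-example
fixtures.

## Known limitations

- The m-weight schedule is exact at the published anchor points but its
  functional form between and beyond them is a calibrated choice; scores
  for m ≳ 15 are effectively p1 under any schedule consistent with the
  published values.
- The snapshot N behind the published examples was calibrated from the
  published scores themselves (the quoted entity counts do not reproduce
  them); analyses of other datasets should use their own network's N.
- The shuffle null randomizes the chemical–gene layer only, per the
  standard procedure; structure in the other layers is held fixed.
- Tie counts depend on the display precision chosen; both reported modes
  are defensible readings of the published tie tallies.
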
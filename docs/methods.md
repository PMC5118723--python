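# Methods

This note documents the statistical model behind `polyploid_eld`, the
choices made where the design was genuinely open, and the limits of what the
synthetic validation can show.

## The experimental design being modeled

An allopolyploid (e.g. *Raphanobrassica*, genome RRCC) and its two
progenitors — the maternal parent contributing one subgenome (role **A**)
and the paternal parent contributing the other (role **B**) — are each
sequenced as a **single** bulk library, for mRNA and again for small RNA.
The data for one feature type are therefore a features × 3 table of read
counts with library totals `n_A`, `n_B`, `n_C`. No biological replication
exists, which dictates most of the methodology below.

## Normalization and fold changes

Counts are normalized to CPM (`count · 10⁶ / library_size`) or, when
feature lengths are supplied, RPKM (`count · 10⁹ / (library_size ·
length)`). Fold changes between conditions x and y are
`log₂((x + c) / (y + c))` on normalized values with pseudocount `c = 1`
(configurable); the pseudocount bounds ratios of lowly expressed features
and makes `0/0` evaluate to 0.

## Two-library differential expression

With one library per condition, testing reduces to comparing two binomial
proportions `k₁/n₁` vs `k₂/n₂`. The default test is **Fisher's exact
test** on the 2×2 table `(k₁, n₁−k₁; k₂, n₂−k₂)`, two-sided by summing all
tables with the margins fixed whose probability does not exceed the observed
table's (the `fisher.test`/`scipy` convention, with a 1e-7 relative tie
tolerance). The implementation enumerates the full hypergeometric support
in vectorized log-gamma arithmetic, so whole-transcriptome batches against
10⁷-read libraries run in seconds; it is validated in the test suite against
both `scipy.stats.fisher_exact` and exhaustive binomial-coefficient
enumeration. A delta-method z-test on the log ratio of proportions is
available (`method="ztest"`) as a cheaper approximation.

Multiple testing uses Benjamini–Hochberg step-up adjustment (via
`statsmodels`), checked in the tests against the hand-applied formula.

Default call thresholds follow common practice for this design:

| feature | fold criterion | significance | comparison style |
|---------|---------------|--------------|------------------|
| mRNA    | \|log₂FC\| ≥ 1 | raw p ≤ 0.05 | inclusive |
| miRNA   | \|log₂FC\| > 1 | BH q < 0.01  | exclusive |

Both are `DEThresholds` instances and fully configurable.

## Non-additive expression (mid-parent test)

The additive expectation for the polyploid is the mid-parent value
`MPV = (A + B)/2` of the parents' normalized expression. A feature is
**non-additive** when `|log₂((C + c)/(MPV + c))| ≥ 1` and the exact test of
the polyploid count against the **pooled parental counts** (`k_A + k_B` out
of `n_A + n_B`) gives p ≤ 0.05. Pooling the parents' libraries is the
natural exact-test construction of the "C differs from the parental
average" null, since the pooled proportion estimates the mid-parent
proportion when library sizes are equal; it is a documented choice, not
forced by the definition.

## 12-category classification and expression-level dominance

Each feature gets a trichotomous direction call (less / equal / greater)
for the three pairwise comparisons A-vs-B, C-vs-A and C-vs-B. The 27
triples map onto the classical twelve categories plus `no_change`; exactly
13 triples are coherent (they admit an ordering of A, B, C) — 2 additive,
2 ELD-a, 2 ELD-b, 3 transgressive-up, 3 transgressive-down, 1 no-change —
and the remaining 14 (e.g. C = A, C = B, A > B) are statistically
intransitive. These are labeled `conflicting`, reported separately and
excluded from dominance totals; silently reassigning them would bias the
counts.

**Direction calls for classification are significance-only** (exact-test
p ≤ α per pairwise comparison, fold filter disabled), with per-comparison
α = 0.01. Two reasons:

1. *A fold filter makes the additive categories unreachable.* The MPV
   satisfies `MPV / max(A, B) > 1/2` for every parental pair, so a gene
   expressed exactly at its mid-parent value can never appear two-fold
   below its higher parent. Under a two-fold call criterion, categories
   I/XII cannot occur; truly additive genes are absorbed into the
   dominance classes. Classification therefore follows the
   significance-based convention of the category framework.
2. *α = 0.01 per call controls leakage from `no_change`.* A truly
   unchanged gene leaves the no-change category when any of its three
   calls rejects; at α = 0.01 that happens for ≲ 3% of unchanged genes
   (the exact test is conservative), comfortably bounding spurious
   dominance calls.

DE reporting keeps the study-style thresholds above; the classification
thresholds are a separate configurable `DEThresholds` object.

Sub-numbering inside the two-sided groups is fixed as I: A>B, XII: A<B,
III: A>B, X: A<B, V: A<B, VI: A>B (II/XI/IV/IX are determined by their
definitions). Only aggregate classes feed summaries, so no reported total
depends on this convention.

ELD-a (maternal dominance) is patterns II + XI, ELD-b (paternal) IV + IX;
the maternal-bias ratio is `ELD-a total / ELD-b total`. Percentages are
displayed rounded **half-up** to two decimals everywhere and are always
recomputable from the reported numerator and denominator (note that sources
sometimes truncate instead: 4467/9209 = 48.5069% prints as 48.51 here).

## miRNA–mRNA anti-correlation network

Given predicted miRNA→gene target pairs, an edge is retained for comparison
X ∈ {C-vs-A, C-vs-B} when **both** the miRNA and the gene are called
differentially expressed in X with opposite directions. Significance in
different comparisons does not create an edge. The two comparisons' edge
lists are merged as a multiset; distinct-gene totals use the set union.
Per-miRNA tallies (related-target counts, non-additive fractions, edge
shares) are sorted by decreasing target count. Same-direction pairs can be
kept in a side table but never enter summaries.

## Enrichment

Term over-representation is the hypergeometric upper tail
`P(X ≥ k)` for k study hits of a term with K population hits, study size n,
population N (population defaults to all detected features), with BH across
the tested terms and significance at q ≤ 0.05. The additive-vs-non-additive
per-term comparison uses the two-sided exact test on
`(hits_a, size_a−hits_a; hits_b, size_b−hits_b)` — the secondary-
classification bar-chart comparisons never name their test, so this exact
2×2 construction is the package's documented choice. Slim tabulations count
distinct features per (namespace, level-2 term) from a supplied term→slim
map; no GO DAG propagation is performed.

## Synthetic data generator

`simdata.simulate_counts` plants per-gene aggregate classes
(no-change / additive / ELD-a up/down / ELD-b up/down / transgressive
up/down) and builds expected CPM means from a per-gene base `b` and the
effect size `e = 2^effect_log2fc` exactly as tabulated in the module
docstring; e.g. ELD-a-up means `B = b, A = C = b·e`, additive means
`C = (A+B)/2` with a fair coin deciding the high parent, transgressive
classes use equal parents. Defaults:

* `n_genes = 10,000`, `n_mirnas = 300`, `library_sizes = 10⁷` each —
  detected-feature and library scales of a typical bulk study of this kind
  (the acceptance script and tests use these sizes; the end-to-end runtime
  check uses 20,000 genes);
* `effect_log2fc = 2` (four-fold planted effects, two-fold-threshold
  detectable with margin);
* `base_mean = 200` CPM with per-gene bases drawn log-uniformly over
  `[base_mean/10, base_mean·10]` for a realistic dynamic range;
* `dispersion = 0.05`;
* class proportions: 55% no-change, 10% additive, 9% ELD-a, 8% ELD-b,
  18% transgressive — unchanged genes dominate, with a maternal tilt among
  dominance classes, mirroring reported compositions;
* `targets_per_mirna = 3`, `anticorrelated_fraction = 0.3`.

**Noise model.** Gene-level expression heterogeneity is a gamma latent
factor with mean 1 and variance φ (= `dispersion`) **shared across the
three libraries** of a gene; given the factor, each library's count is
Poisson at `mean · library_size/10⁶`. Marginally every count is negative
binomial with variance `m + φm²`; conditionally the three libraries are
Poisson samples of their planted means, which is exactly the sampling
situation the replicate-free exact test assumes. φ = 0 degenerates to plain
Poisson. This is a deliberate modeling decision: the emulated design has no
biological replicates, so between-individual variance is not identifiable
from the real data either.

**What passing tests do and do not show.** Planted-truth recovery and
type-I control on this generator validate the *pipeline logic and the
tests' own assumptions* — thresholds, decision tables, set algebra,
calibration under conditional-Poisson sampling. They do **not** show that
single-library exact tests are calibrated on real organisms: if biological
noise varied independently between the polyploid and parent individuals,
any replicate-free test would be anti-conservative and the printed p-values
optimistic. That is a limitation of the emulated study design itself, not
of the implementation, and is the main caveat when interpreting real-data
results.

**Truth labels.** Planted DE directions are derived from the planted means
with the two-fold rule, non-additivity truth from the planted `C` vs planted
MPV, and the anti-correlated truth set from pairs whose planted directions
oppose within a comparison — including pairs that landed opposite by chance
rather than by planting.

## Numerical details

* Exact-test tie handling: tables with pmf ≤ observed·(1 + 1e-7) are
  summed (matches R and scipy); support sums are computed from a cached
  log-gamma table, scaled by the per-support maximum to avoid overflow.
* BH is statsmodels' `fdr_bh`; q ∈ [p, 1], stable under input permutation.
* Degenerate inputs: all-zero features give p = 1 and log₂FC 0 (pseudocount);
  empty networks/summaries return explicit all-zero structures; duplicate
  ids, negative counts, missing roles and mismatched feature universes
  raise typed errors naming the offender.
* Determinism: one `numpy` `Generator` seeded from `SimulationConfig.seed`
  drives every draw; identical configs give byte-identical outputs, and the
  pipeline itself is deterministic given fixed inputs.

## Known limitations

* No replicate-aware inference (impossible under the emulated design).
* The conflicting category has no downstream interpretation beyond being
  counted.
* Enrichment assumes the annotation and slim map are complete and correct;
  no ontology reasoning is attempted.
* TF-family means use total expression over expressed members only, which
  overstates family expression when many members are silent (kept because
  it is the estimator the summaries are defined with).
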
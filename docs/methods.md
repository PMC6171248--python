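# Methods

## The question and the inference chain

Given a set of genomes, an isolation-environment label for each, and
all-vs-all protein similarity searches, the package asks whether gene
content groups genomes by environment beyond what shared ancestry predicts.
Two complementary orderings of the same genomes are built and compared:

* a **phylogenetic background** — neighbor-joining on `1 − GSS`, where the
  genomic similarity score aggregates reciprocal-best-hit (RBH) bitscores,
  plus (when available) an externally supplied reference phylogeny; and
* a **content ordering** — agglomerative clustering of Jaccard distances
  between per-genome functional profiles.

Congruence between the two is quantified with Robinson–Foulds symmetric
differences and the adjusted Rand index; environment signal is quantified
with hypergeometric cluster–environment enrichment under FDR control; and
the specific families driving it are isolated as "adaptive" functions.

## Orthology and the GSS

RBHs are computed per genome pair after removing alignments with query
coverage < 0.70 (the filter runs before best-hit ranking; the reverse order
is available behind a flag).  Bitscore ties are broken deterministically by
percent identity, alignment length, then subject ID.  Multi-genome ortholog
groups are anchored on a reference genome (lexicographically first by
default): each reference gene defines one group of its RBH partners.  This
anchored construction was chosen over connected components because it keeps
"present in all/most genomes" unambiguous; families absent from the
reference are therefore not enumerated, which is the same asymmetry the
anchored phrasing of core-genome counting implies.  Occupancy thresholds use
`ceil(t · n)` members, so "at least 70%" is exact at any n.

The GSS is computed as the ratio of summed reciprocal cross-scores to summed
self-scores over a pair's RBHs.  The published score this stands in for has
a normalization we do not reproduce (its definition lives in sources outside
the analysis chain implemented here); the ratio form used is symmetric,
bounded in [0, 1], equals 1 for identical genomes, and 0 for genomes without
RBHs.  It is documented as an approximation, not the original formula.

Neighbor joining follows Saitou–Nei with the Studier–Keppler O(n³) update.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sister branch, preserving the joined pair's distance (Phylip
behaviour).  On additive matrices the implementation is exact in both
topology and branch lengths (verified against independently generated random
trees, n ≤ 10).

## Profiles, clustering and quality metrics

Domain assignments are filtered by PSSM coverage (≥ 0.70) and then
de-overlapped per protein, greedily retaining higher scores first and
dropping an assignment when it overlaps a retained one by more than 10% *of
the shorter interval* (1-based inclusive coordinates).  The overlap
denominator is a genuine open choice — the shorter interval is the strictest
common convention and is configurable (`longer` is also provided).
`J(∅,∅)` is defined as 1: two genomes with no surviving annotations are
indistinguishable, and this is flagged with a warning rather than an error.

Clustering uses scipy's Lance–Williams implementation.  `ward` on a distance
matrix corresponds to **Ward.D2**; it is applied to Jaccard distances even
though they are not Euclidean, because the dendrogram here is a descriptive
device whose quality is judged by the agglomerative coefficient
(`AC = 1 − mean(first-merge height / final height)`, in [0, 1]) and by
silhouette widths, not by a Euclidean embedding.  Cuts undo the last k − 1
merges, making successive partitions exactly nested; cluster labels follow
leaf appearance order for reproducibility.  Silhouettes for singleton
clusters are 0 by convention.

## Association statistics

Cluster–environment association uses the one-sided hypergeometric
over-representation tail (scipy's survival function, cross-checked against
exhaustive enumeration for all N ≤ 12).  The dendrogram is cut at
k = 3, 4, ...; within each cut, all cluster × environment p-values are
Benjamini–Hochberg adjusted and the scan stops at the first cut with no
q ≤ α.  FDR scope is per cut by default — each cut is the unit of inference
that gets reported — with a pooled-across-cuts option, since the scope is
not dictated by the procedure itself.  Environments covering zero or all
genomes yield no contrast and are skipped.

Adaptive-function detection replaces count-model regression with an exact
one-sided 2×2 presence test per (function, focal group) — focal group vs the
union of the others by default, or all ordered group pairs in `pairwise`
mode — followed by BH adjustment across all contrasts.  The reporting gates
are kept at q ≤ 0.05 and focal presence ≥ 0.80.  The exact-test proxy trades
the frequency (copy-number) information a Poisson model would use for
distribution-free behaviour on presence/absence profiles, which is the data
this package's profiles carry.

## The simulator: what it emulates and what it does not

The generator's defaults are the package's reference study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_genomes` | 60 | tips of a pure-birth (Yule) tree, `birth_rate` 1.0 |
| `n_environments` | 3 | clade-wise classes from a closed 5-label vocabulary |
| `polyphyly_events` | 3 | tips re-labelled *into* each environment |
| `core_size` | 150 | universal families, never lost |
| `ancestral_accessory` | 80 | ancestral families subject to loss |
| `gain_rate` | 0.4 /unit length | Poisson novel-family gains per branch |
| `loss_rate` | 0.15 /unit length | per-family exponential loss |
| `pool_size` | 30 | planted convergence families per environment |
| `pool_gain_prob` | 0.9 | per-tip acquisition probability from the pool |
| `bitscore_decay` | 0.05 /unit distance | exponential score decay |
| `noise_sd` | 5.0 bits | Gaussian score noise (self-scores ≈ 300–1200) |
| `low_coverage_frac` | 0.10 | families aligning below the 0.70 coverage floor |
| `spurious_rate` | 0.02 | low-scoring cross-family hits |

Design choices worth recording:

* **Infinitely-many-genes gains.**  Every gain event creates a brand-new
  family, so any homoplasy in the simulated data is attributable solely to
  the planted pools, which are disjoint from vertical families and from each
  other.  This gives recovery tests an unambiguous ground truth at the cost
  of excluding re-gain of lost families.
* **Balanced clade-wise environments.**  The k monophyletic blocks seeding
  the labels are chosen by a tree DP that maximizes the smallest block,
  emulating the comparably sized isolation classes of real isolate
  collections; polyphyly is then injected by re-labelling tips across
  blocks, and both the pre-reassignment clade labels and the moved tips are
  recorded as ground truth.
* **Ultrametric truth makes the GSS distance benign.**  Yule trees are
  ultrametric, and with noise-free scores the pairwise GSS equals
  `exp(−decay · d)` exactly, so `1 − GSS` is a monotone transform of an
  ultrametric — itself additive — and NJ recovers the generating topology;
  score noise and coverage filtering perturb this only mildly.  This is why
  tree recovery is tested at RF ≤ 2 rather than demanding exactness.
* **Family-level alignment coverage.**  Coverage has a family-level base
  (10% of families below the 0.70 floor) plus ±0.02 per-hit jitter, so the
  coverage filter removes whole families — mimicking genuinely
  hard-to-align families — rather than punching independent random holes
  through the core, which would make occupancy-1.0 families vanishingly
  rare at realistic genome counts.
* **Function assignments mirror family truth.**  The assignment table gives
  every gene its family as its function at high PSSM coverage, plus a small
  fraction of heavily overlapping (filtered) and non-overlapping (retained)
  secondary domains.  Sub-threshold PSSM coverage is exercised by dedicated
  unit fixtures instead of being planted in the bundle, so profile presence
  reflects planted content.
* **Determinism.**  A single seed is split into independent per-stage
  substreams (tree / environments / content / hits / assignments); identical
  configurations reproduce every output byte-identically, including fixture
  bundles and full pipeline output directories.

What the simulator does **not** model: nucleotide/protein sequences and
realistic BLAST statistics, paralogy and gene families with copy number,
plasmids, rate heterogeneity across lineages, and correlated gain of
functionally linked genes.  Passing recovery tests therefore shows the
chain's statistics behave correctly under their own assumptions — planted
convergence is found, phylogeny is recovered, null labels yield no calls —
not that real annotation pipelines are error-free.

## Problem sizes and numerical choices

Tests and the acceptance script run the full chain at 60 genomes
(≈ 7 × 10⁵ directed hits, 1 770 genome pairs), which exercises every code
path in well under a minute per arm on one core; oracle comparisons use
exhaustive enumeration at small n (RF n ≤ 8, hypergeometric N ≤ 12, naive
agglomeration n ≤ 7) where brute force is feasible.  Distance matrices are
validated for symmetry (atol 1e-8), NaNs and zero diagonals; GSS values are
clipped into [0, 1] against score noise; merge-tie determinism comes from
stable sorts and documented tie-break keys.  The association scan under
permuted labels holds its false-positive rate within Monte-Carlo error of
the nominal α (1 000 replicates): with phylogenetically *structured* labels
and no pools, content clusters still associate with environments through
shared ancestry — that is a real property of the statistic, not an error —
so the no-signal check uses permuted labels.

## Known limitations

* The GSS here is a documented stand-in, not the published normalization;
  absolute GSS values should not be compared against other software, though
  orderings are very similar in practice.
* Reference-anchored grouping undercounts families absent from the
  reference genome; choose the reference deliberately on real data.
* Ward.D2 on non-Euclidean Jaccard distances has no variance
  interpretation; use `average`/`complete` linkage if that matters.
* The adaptive-function test ignores copy number and within-group
  correlation (phylogenetic non-independence of genomes); its q-values are
  calibrated for independent presence draws only.
* The simulator's hit tables have no paralogs, so RBH tie-breaking is only
  exercised by injected spurious hits.
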
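# Methods

## The model

The unit of analysis is the *bioset*: the set of gene symbols called
differentially expressed in one case/control comparison, annotated with its
experiment of origin and tissue. The pipeline asks whether any subset of
biosets — ideally spanning experiments and tissues — shares enough genes to
constitute a common regulatory signature, and whether that sharing exceeds
what study-level batch structure and chance co-occurrence produce.

Relatedness between biosets is the Jaccard coefficient on gene sets. Two
properties motivate it: it is defined directly on binary presence/absence
data, and shared absence contributes nothing, so two lists are similar only
through the genes they both contain. Two empty sets are assigned similarity
0 (distance 1): degenerate biosets should not cluster with each other.

## Clustering

Agglomerative clustering on d = 1 − J, with average linkage by default.
The linkage is configurable (single, complete) because no single choice is
canonical for set-similarity dendrograms; average linkage is the default
here since it tracks the mean between-group Jaccard distance, which is the
quantity the stability analysis later resamples. The merge loop is a direct
O(n³) Lance–Williams implementation rather than a library call for one
contractual reason: binary data produce tied distances routinely, and we
require a documented, deterministic tie-break — among pairs at the minimal
distance, the lexicographically lowest pair of cluster indices (leaves in
input order, internal nodes in merge order) merges first — so trees and
partitions are bit-reproducible. scipy's implementation serves as an
independent oracle in the test suite on tie-free inputs. With the three
supported linkages the merge heights are automatically nondecreasing, so
cutting into k clusters by undoing the k−1 last merges (in merge order,
which resolves ties) is well defined.

Classical MDS (double-center −½d², eigendecompose, scale eigenvectors by
√λ) is provided as a visualization of the same dissimilarities; Jaccard
distances are generally non-Euclidean, so negative eigenvalues are
truncated to zero with a warning.

## DE selection

When raw case/control tables are the input, a gene is selected iff a
two-sided t-test (Welch with Satterthwaite degrees of freedom, or Student;
paired reduces to the one-sample test on differences) gives p < 0.05
*unadjusted*, and the signed linear fold change — ratio of case to control
group means, reported as −1/r when r < 1 — has magnitude ≥ 1.2 (inclusive).
Conventions for degenerate inputs: zero variance in both groups with equal
means gives p = 1; with unequal means p = 0. No multiple-testing correction
is applied at this stage, deliberately: the thresholds are sensitivity-
oriented so that list sizes remain comparable across biosets, and the
cost — an expected ~5% per-gene false-positive rate under the null, further
reduced by the fold-change gate — is accounted for downstream, where the
analysis operates on set overlaps rather than individual calls. Fold change
is computed on linear-scale group means (not medians, not log-means); this
is the convention under which the generator's log-additive effects are
exactly interpretable.

## Bootstrap stability

Clusterwise stability follows the nonparametric bootstrap scheme for
partition validation: draw n biosets with replacement, recluster the
resample with the same linkage and the same k as the original partition,
and score each original cluster by the maximum Jaccard similarity between
its member set and any bootstrap cluster's member set, both expressed in
original bioset identities (bootstrap duplicates collapse). The original
cluster is first restricted to the members actually drawn. The mean over B
runs is the stability index; > 0.6 is treated as robust, ≤ 0.5 as
dissolved. k is held fixed across bootstrap reclusterings to match the
original partition's granularity. Defaults: B = 1000, k = 14,
thresholds 0.6/0.5.

Runs in which *no* member of a cluster was drawn are excluded from that
cluster's mean by default and reported as a separate count
(`n_empty_draws`). Such runs carry no information about the cluster's
coherence — counting them as similarity 0 penalizes clusters, particularly
small ones, for sampling absence alone (a cluster of m of n biosets is
entirely absent with probability ≈ (1−m/n)^n, about 2.6% per run for a
triplet of 27, which would cap even a perfectly reproducible cluster's
index near 0.97). The strict all-B mean is available via
`skip_empty_draws=False` for comparability with tools that count such runs.
A related consequence of resampling worth knowing: even exact duplicate
biosets do not yield an index of exactly 1, because a resample that omits
one group entirely forces the fixed-k cut to split a zero-distance group
elsewhere; for three identical triplets the index lands above 0.99, not at
1.0.

Randomness: `numpy.random.default_rng` seeded from the config; per-run
generators derive from `SeedSequence(seed).spawn(B)`, so reports are
bit-identical across platforms and any single run can be reproduced in
isolation. Because a resampled bioset is an exact copy of its original,
bootstrap distance matrices are index-gathered from the original distance
matrix rather than recomputed.

## Root signature and specificity

The root of a cluster is the set of genes present in all member biosets
(strict intersection, `min_support=1.0`). When per-bioset inclusion is
itself noisy — a gene truly in the shared program still misses any one list
with some probability — strict intersection under-recovers geometrically
in the number of members (inclusion 0.95 over 5 members retains only
0.95⁵ ≈ 77% of the program), so a support threshold is exposed:
`min_support=0.8` keeps genes present in ≥ ⌈0.8·m⌉ members (expected
recovery ≈ 98% in the same regime, while background genes remain very
unlikely to reach 4-of-5 support). The end-to-end analyses in this package
use 0.8 for planted-signature recovery for exactly this reason; strict
intersection remains the default for real-data use where the inclusion
process is unknown.

Specificity is assessed by (a) the distribution of signature content in all
pairwise intersections of an unrelated corpus — under independent
Bernoulli(p) lists its expectation is |signature|·p², a useful sanity
anchor; (b) direct intersection with reference lists (e.g. housekeeping
genes), where large overlap would argue the signature is generic; and
(c) one-sided hypergeometric over-representation tests (the upper tail of
Fisher's exact test), with fold enrichment (k/m)/(r/N) and BH-FDR across
batches of references. The enrichment universe defaults to the union of all
corpus genes and is configurable, since any externally curated universe is
a modeling choice of its own.

## The synthetic generator

`generate_list_corpus` emulates the structure such a meta-analysis actually
faces: a low baseline probability that any gene enters any list (chance
overlap), per-experiment gene blocks entering that experiment's biosets
with higher probability (batch structure — the force that makes biosets
cluster "by experiment first"), and an optional planted signature pushed
into designated biosets across experiments. When a gene is covered by
several effects the maximum probability applies — chosen over
union-of-independent-events because it keeps every marginal inclusion
probability exactly equal to a spec parameter, which the goodness-of-fit
tests exploit. The generator emits a ground-truth manifest (gene roles,
designated biosets, and the background genes that by chance entered every
designated bioset — the exact excess a strict-intersection root picks up),
enabling parameter-recovery tests with no circularity.

`generate_expression_corpus` produces log-additive intensity matrices
(gene baseline + experiment effect + optional per-gene tissue offset +
case×log-fold effect on designated genes + Gaussian noise, exponentiated),
so that with zero noise the linear fold change of a designated gene is
exactly the nominal effect. Deliberately not modeled: platform/probe
effects, normalization artifacts, covariates (age/sex), and correlated
noise. Passing tests therefore demonstrate correctness of the *procedure*
under a clean membership/intensity model, not robustness to real-data
artifacts.

### Study-scale working conditions

The end-to-end recovery analysis uses 27 biosets in 9 experiments of 3 over
a 2000-gene universe, baseline inclusion 0.05, and a 66-gene signature at
inclusion 0.95 in 5 biosets spanning 3 experiments, clustered at k = 14
with B = 200 bootstrap runs. The batch-structure parameters (60
experiment-specific genes per experiment, share probability 0.7) were fixed
by closed-form expectation before any end-to-end run: they give
within-experiment Jaccard ≈ 0.14 versus cross-experiment background ≈ 0.02
(batch structure dominates chance) while planted-signature pairs reach
≈ 0.19 (the signature dominates batch structure), which is the regime the
method is for. B = 200 keeps the bootstrap Monte-Carlo error of a stability
index near 0.02 while the full analysis runs in seconds on one CPU.

## Numerical and edge-case choices

- Symbol normalization everywhere: uppercase, strip, deduplicate; no live
  nomenclature lookups.
- p-cutoff strict (<), fold-change cutoff inclusive (≥).
- Stability thresholds: robust strictly above 0.6, dissolved at or
  below 0.5.
- `hypergeom.sf(k−1, N, r, m)` for the upper tail; p clipped to [0, 1].
- Column order of the binary matrix lexicographic; row order input order;
  Newick branch lengths are parent minus child merge height, so
  root-to-leaf path length equals the root height.
- Distance matrices are validated (symmetry, zero diagonal) before
  clustering or MDS; non-symmetric input is an error, not silently
  symmetrized.

## Known limitations

- The O(n³) agglomeration and O(n²) pairwise distances are intended for
  corpus sizes in the tens to low hundreds of biosets, which is the regime
  of list-level meta-analysis; they are not suitable for thousands of
  observations.
- Stability is assessed for a fixed k supplied by the analyst; the pipeline
  does not select k.
- The overlap null treats biosets as exchangeable; real corpora have
  correlated membership (shared platforms, labs) that the Bernoulli
  expectation does not capture.
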
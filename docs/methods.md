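# Methods

## Association measure

The gene–metagene association J is normalized, rectified mutual
information. Expression vectors are soft-binned with a clamped uniform
B-spline basis (default B = 6 basis functions of order 3): each
observation is scaled linearly onto the spline domain and spread over the
basis functions, which form a partition of unity, and the plug-in MI is
computed from the resulting fractional joint histogram. Soft binning
stabilizes the estimate on sparse, zero-inflated log-normalized data; a
hard equal-frequency estimator (`estimator="hard_bin"`) is provided as an
exact reference for discrete data and is used by the test oracles.
Vectors with fewer distinct values than B use one bin per distinct value,
which makes the hard estimator *exactly* the discrete plug-in MI there.
Ties at an equal-frequency boundary go to the lower bin, so binning is
deterministic and invariant to monotone relabeling of the values.

Normalization divides I(x, y) by min(I(x, x), I(y, y)) under the same
estimator. Under hard binning the self-information I(x, x) equals the
plug-in entropy H(x), recovering the familiar I/min(H(x), H(y)) form;
under soft binning I(x, x) < H(x) because neighbouring bins share mass,
and dividing by the entropy would make self-association less than 1.
Dividing by the self-information keeps the defining property J(x, x) = 1
for every non-constant vector under both estimators. J is clamped to
[0, 1] and set to 0 when either vector is constant or (with
rectification, the default) when the Pearson correlation is negative —
only the sign is consulted, so Pearson suffices.

## Attractor iteration

On a log-normalized, gene-filtered matrix, one step maps a metagene m to

    w_i = J(x_i, m)^a / sum_j J(x_j, m)^a,    m' = sum_i w_i x_i.

The exponent a sharpens the weighting. Iteration stops when:

- **converged** — the top-K gene set by J (K = 50) is identical between
  successive iterations. Set stability is used rather than a norm
  tolerance because the deliverable is a ranked list; the reported
  metagene is the one that produced the final J profile, so one further
  step reproduces the top-K set exactly.
- **degenerate** — fewer than `min_support` (10) genes have J > 0, or a
  single gene holds more than `dominance_threshold` (0.5) of the weight.
  A one-gene "signature" is not co-expression.
- **oscillating** — a previous top-K set recurs within a sliding window
  of 4 iterations.
- **max_iter** — the cap (50) is reached.

**Initialization.** The metagene starts at the mean expression of the
seed's `min_support` most-associated genes (the seed itself ranks first
with J = 1), not at the raw seed vector. Starting from the raw vector is
a known trap: the seed's self-association is exactly 1, so at any
exponent above 1 its weight dominates the update and the iteration fixes
on the seed alone — precisely the collapse the dominance guard exists to
flag. The neighborhood mean starts the iteration at an actual
co-expression candidate while using only the same association measure;
on planted-module data the iteration then reaches the module fixed
point, which is self-sustaining (every module gene's J against the
module-mean metagene is far above background, and no single gene
dominates).

**Adaptive exponent.** The grid {2, 3, 4, 5, 6, 8, 10} is swept from the
smallest value upward. Among converged, non-degenerate runs the one
maximizing *signature strength* — the J of the rank-`min_support` gene —
is returned, with the chosen exponent recorded. Strength measures how
tightly the signature's core co-expresses; maximizing it favours the
sharpest exponent the data can support. If no exponent converges, the
strongest non-converged result is returned (with its status) instead of
raising, so seed scans degrade gracefully. On the benchmark data small
exponents converge while large ones collapse onto one gene and are
discarded as degenerate.

**Scanning and deduplication.** `scan_attractors` runs every seed (an
explicit gene list, or the most variable genes — `n_variance_seeds`,
default 2000, bounds the cost), keeps converged results, sorts them by
strength and greedily merges any result whose top-K set has Jaccard
similarity ≥ 0.5 with an already-kept one. Ranking ties anywhere in the
package break lexicographically by gene identifier, so results are
platform-independent.

## Consensus ranking and overlap testing

Per-sample ranked lists are aggregated by *support* (number of samples
placing the gene in the top k) first and median rank second, with
absence from a sample's top k penalized as rank k + 1. Support-first
ordering encodes that cross-sample reproducibility outranks a good rank
in a single sample; the bounded penalty keeps samples with different
list lengths comparable. The result is invariant to sample order.

The overlap test is the one-sided upper-tail hypergeometric probability
of seeing at least the observed intersection between two lists drawn
from a universe of N genes, accumulated in log space (logsumexp of
log-pmf terms) so that p-values far below the underflow threshold of a
single term remain accurate. No multiple-testing correction is applied
inside the operation; that is the caller's concern. When testing lists
against a filtered matrix, the natural universe is the number of genes
surviving the expression filter; for published lists the universe must
be supplied explicitly, and conclusions can be sensitive to it.

## Signature scoring and abundance

A cell's score is the mean across signature genes of the gene's z-scored
log-normalized expression. Zero-variance genes contribute 0 rather than
being dropped, keeping scores comparable across matrices; scores are
invariant to per-gene affine rescaling, and their population mean is ~0.
The signature-positive fraction is estimated by fitting a two-component
1-D Gaussian mixture (scikit-learn, k-means initialization, fixed random
state 0) and thresholding at the point of equal posterior probability
between the components, found by root-bracketing between the component
means; if the posteriors do not cross there (a near-degenerate fit), the
midpoint of the means is used. A fixed threshold can be supplied
instead, and is required below 10 cells.

## Synthetic data

The generator emulates a dissociated-tissue (SVF-like) counts matrix:
per-gene baseline means are log-normal (meanlog 0, sdlog 1 — means
centred near 1 count with a heavy right tail), per-cell size factors are
log-normal (sdlog 0.3, ~±35% library-size spread), and counts are
negative binomial with variance μ + μ²/θ (θ = 2, strongly
overdispersed; θ → ∞ is the Poisson limit). Each planted module is a
block of genes whose means are multiplied by a common fold (4) in the
cells of a latent sub-population (a 20% fraction by default), which
induces module co-expression across cells and provides ground-truth
labels. The canonical benchmark is 2000 genes × 1000 cells with one
30-gene module, seed 1; it is roughly 45% zeros. All randomness flows
through one seeded generator in a fixed order (gene means, size factors,
labels, counts), so output is bit-reproducible and partial regeneration
is impossible rather than subtly wrong.

What the simulator does **not** model: doublets, ambient RNA, batch
effects, gene-length or GC bias, gradual (non-discrete) population
structure, and correlated noise outside the planted modules. Passing the
planted-module benchmarks therefore shows that the algorithm recovers a
discrete co-expressed module under realistic sparsity and
overdispersion; it does not show robustness to those unmodeled
artifacts, and on real tissue the recommended practice is the one the
consensus module encodes — derive signatures per sample independently
and keep what reproduces.

## Numerical and interface choices

- Counts are log-normalized as log1p(count / cell-total × 10⁴); the
  scale is configurable. All-zero cells are dropped with a warning.
- Genes expressed in fewer than 2% of cells are filtered before
  attractor analysis: MI estimates on near-all-zero genes are noise.
- Duplicate identifiers in input files are suffixed `.1`, `.2`, … in
  file order with a warning; matching is exact and case-sensitive.
- Gene-list intersections preserve first-list order and may be empty
  in memory; reading an empty gene-list file is an error.
- MatrixMarket input is 1-based per that standard; everything in memory
  is 0-based. 10x feature tables use the symbol column when present.
- The MI workspace precomputes each gene's bin weights once per matrix
  (one GEMM per profile evaluation thereafter), which is what makes
  whole-matrix seed scans practical.

Problem sizes used by the test suite and the acceptance script: the
2000 × 1000 benchmark (single- and two-module variants, with 60
variance-ranked seeds for the scan), a 500 × 300 instance for fast unit
tests, 200 cells for permutation-invariance checks, exhaustive estimator
oracles over all ternary length-6 vector pairs and all hypergeometric
configurations with N ≤ 12.

## Known limitations

- The attractor finds one module per basin; overlapping modules (a gene
  in two programs) are out of scope, and the simulator enforces disjoint
  modules.
- The mixture-based abundance estimate assumes a roughly bimodal score
  distribution; for weak signatures (fold near 1) the threshold is
  ill-defined and a fixed threshold should be preferred.
- Soft-binning MI is biased upward for very short vectors; with fewer
  than ~50 cells the hard-bin estimator with few bins is the safer
  choice.
- The exponent grid is discrete by design (reproducibility over
  marginal optimality); continuous exponent optimization is deliberately
  not provided.
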
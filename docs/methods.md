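# Methods

## Data model

A monitoring table is an information system: `n` samples × `d` continuous
condition attributes plus one continuous decision attribute (per-phylum
chlorophyll quantity). Rows with missing or non-numeric cells are dropped at
load time and counted, the only cleaning performed. Attributes are min–max
scaled to [0, 1] for the distance-based predictors (constant columns map to
0); scaling parameters are fitted on training data and reused for test
samples. Correlation ranking runs on raw values — the Pearson coefficient is
scale-invariant.

Granular-ball purity needs class labels, but the decision attribute is
continuous and no discretization rule is inherent to the method; we
quantile-bin it into `q = 3` classes (configurable), ties assigned to the
lower bin, and use the labels *only* inside the reduction — regression always
targets the raw values. When fewer than `q` distinct values exist, `q` is
reduced with a warning.

## Granular-ball partitions

A ball is summarised by its center (mean of members) and radius (mean
member-to-center Euclidean distance); a singleton has radius 0. Generation
starts from one ball over all samples under the chosen attribute subset and
repeatedly splits any ball whose purity (majority-label fraction) is below
the threshold and whose size exceeds `min_size`:

* split = 2-means, seeded at the two members farthest apart (first such pair
  in row-major order on ties), Lloyd iterations until the assignment is
  stable, distance ties to the first center. The procedure is fully
  deterministic; no random initialization is used, which we prefer over
  fidelity to any particular stochastic implementation.
* a ball whose member coordinates all coincide cannot split and is flagged
  unsplittable; with conflicting labels it is never counted as covered.
* an empty-cluster outcome falls back to the farthest-pair seeding itself.

Membership is by construction (each sample belongs to the ball whose
splitting lineage it followed), not by the geometric test `‖x − c‖ ≤ r`: with
mean-distance radii roughly half of the members of a ball lie outside its
radius, so geometric membership would leave samples uncovered. This is a
known representational quirk of mean-radius granular balls; construction
membership keeps the partition a true partition.

Defaults: `purity_threshold = 1.0` (strict positive region), `min_size = 1`
(`n` is tiny; splitting may reach singletons). De-overlap post-processing of
hetero-label balls, present in some granular-ball implementations, is not
implemented; the purity threshold alone governs splitting.

## Rough-set reduction

The balls are the equivalence classes of the indiscernibility relation, so
lower/upper approximations of a decision concept are the unions of balls
wholly inside / intersecting it, and at strict purity the positive-region
size equals both the summed per-class lower-approximation sizes and the
partition coverage — the identity is cross-checked in the tests.

Forward selection makes a single pass over the attributes in column order
(optionally in descending-|ρ| order), tentatively adds each, regenerates the
partition, and retains the attribute iff coverage strictly increases; ties
discard it, and rejected attributes are not retried.

**Singleton guard.** With `min_size = 1` and strict purity, every singleton
ball is trivially pure, so literal coverage saturates toward `n` even on
pure-noise tables (the pathology is demonstrated in the test suite). By
default inside `forward_select` a pure ball therefore counts toward coverage
only if it has ≥ 2 members; `count_singletons=True` restores the literal
count, which remains the default for `positive_region_size` (where the
lower-approximation identity must hold exactly).

**Known limitation.** When labels are noisy — which quantile-binning a noisy
continuous target guarantees near bin boundaries — boundary regions fragment
into singletons and chance-pure pairs. Adding even an irrelevant attribute
re-pairs some of these by chance, so the strictly-greater retention test
admits noise attributes on a substantial fraction of noisy tables (we
measured roughly half of seeds at the generator's default noise level, with
clean recovery approached only as target noise → 0; class-centroid-seeded
splitting and purity-gain stopping rules were evaluated and did not help).
The greedy coverage criterion is therefore a dimensionality reducer rather
than an exact support-recovery procedure; the method-comparison experiments
show it still improves kNN error on ~90% of planted-signal fixtures.

## Pearson machinery

Population (1/n) moments throughout, matching the convention that the
coefficient is the covariance of standardized variables; the intermediate
covariance and standard deviations are exposed for testing (the 1/n vs
1/(n−1) distinction cancels in ρ itself). Zero-variance attributes rank with
ρ = 0 and a warning; a zero-variance target is an error.

The sweep deletes one attribute per step in ranking order and scores every
nested subset by pooled cross-validated RMSE (for kNN, minimised over the k
grid; for the BP network, a single fit per fold). Two removal directions
exist: the conventional one (smallest |ρ| first, default) and a verbatim
variant that removes the largest first (`remove_largest_first=True`) —
the latter discards the most label-relevant attributes early and is kept
for comparability only. "Best" is the lowest RMSE; ties resolve toward
fewer attributes.

## Predictors

**kNN.** Euclidean distance over the condition attributes only — the target
difference printed in some statements of the distance is unknowable at
prediction time and is excluded. Prediction is the unweighted mean of the k
nearest training targets; distance ties break by ascending training-sample
index via a stable sort. The default grid is k ∈ {1,3,5,7,9,11,13,15}.

**BP network.** One hidden layer of width `max(8, 2d)` by default, logistic
hidden activation, linear output, full-batch steepest descent on MSE,
learning rate 0.01, 2000 epochs, seeded Gaussian `N(0, 1/fan_in)` weight
initialization and zero biases — all configurable. Inputs are min–max
scaled and the target is z-scored internally (chlorophyll spans thousands
of units; raw-scale gradients diverge at any sensible rate), with
predictions transformed back. A non-finite loss raises an error naming the
epoch. Analytic gradients are verified against central finite differences
to < 1e−5 relative error.

## Evaluation protocol

RMSE, MAE, MAPE and R² with the sample-size divisor; MAPE excludes
zero-valued actuals and reports the exclusion count (near-zero chlorophyll
readings do occur); R² uses the mean of the actuals and may be negative.
All-zero actuals (MAPE) and zero-variance actuals (R²) are errors.

The default protocol is 5-fold cross-validation, seed 20240223, with
pooled held-out predictions; a single `holdout` split (e.g. 30%) is
available since no canonical protocol exists for tables this small. Any
feature selection is refit inside each training fold; a leakage test in
the suite verifies that shuffling held-out targets changes no selected
subset. If GBRS retains no attribute in a fold, that fold falls back to all
attributes (an empty feature set cannot feed a regressor); the event is
logged.

The PK pipeline reports the full (feature count × k) RMSE grid plus both
the per-k best and the global best cell, since either convention is
defensible. GBRSK reports one score per k with the per-fold selected
subsets recorded. Published tables in this area print integer RMSEs; an
integer-rounding display mode is provided, full precision is the default.

## Synthetic tables

The generator emulates the anatomy of a small river-monitoring record:
`n = 68` samples (monthly cadence switching to sparse quarterly-like
spacing for the last 8), 13 attributes = 3 informative (seasonal sinusoid,
period 12, plus AR(1) irregularity, φ = 0.6) + 4 redundant (affine copies
of informative sources with jitter sd 0.05, giving |ρ| > 0.9) + 6 pure
noise; the target is `scale · exp(0.9 z)` of the standardized linear index
of the informative attributes and the seasonal term (weight 0.5), plus
Gaussian noise of sd 0.2 · scale, clipped at zero — non-negative,
right-skewed, bloom-like. `scale = 2000` puts errors in the
thousands-of-units regime typical of per-phylum chlorophyll tables. Linear
and threshold effects, or an arbitrary callable, may be substituted.

What it does *not* emulate: nutrient–algae dynamics, inter-attribute
causal structure, measurement drift, or the specific identities of the 13
real-world variables. Passing tests on these tables show the machinery is
correct and that selection helps under planted redundancy and noise; they
do not certify predictive skill on any real river.

## Numerical choices

* Quantile bin edges use linear interpolation; boundary values go to the
  lower bin.
* Fold assignment is a seeded permutation striped modulo the fold count, so
  sizes differ by at most one.
* 2-means runs at most 100 Lloyd iterations (always converges far earlier
  on these data).
* All stochastic operations (synthetic generation, folds, MLP
  initialization) flow through `numpy.random.default_rng(seed)`; ball
  generation is deterministic by construction but accepts a seed for
  interface uniformity.
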
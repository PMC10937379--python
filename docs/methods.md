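# Methods

`sigdecon` analyzes somatic mutation spectra: a nonnegative count matrix
*X* (*p* channels × *n* samples, e.g. the 96 trinucleotide-context
single-base-substitution channels) is decomposed as *X ≈ W H*, where the
columns of *W* are mutational signatures (probability distributions over
channels) and *H* holds per-sample activities (exposures). This note records
the models, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## De novo discovery: minimum-volume NMF

Plain NMF under the generalized Kullback–Leibler divergence,
min D(X | WH), is not identifiable: any invertible *Q* with *WQ ≥ 0* and
*Q⁻¹H ≥ 0* gives an equally good factorization, so different random
initializations return different signature sets. We therefore minimize

    D(X | WH) + λ · log det(WᵀW + δI),        δ = 1,

with *W* column-stochastic. The log-det term penalizes the volume of the
simplicial cone spanned by the signatures; shrinking the cone onto the data
removes the rotational ambiguity whenever samples come close enough to the
cone's faces (sparse Dirichlet-like exposures do exactly that).

**Updates.** *H* uses the standard multiplicative KL update. For *W* we use a
majorization–minimization step: the penalty's gradient splits through the
sign decomposition of *Y = (WᵀW + δI)⁻¹* into a convex part (majorized
entrywise by a quadratic via Jensen) and a concave part (linearized), so each
entry solves a scalar quadratic *a t² + b t − c = 0* whose positive root is
the update; *a → 0* recovers the plain KL update. After every *W* step the
columns are L1-normalized exactly (scale moved into *H*) and a backtracking
line search (step halving, at most 20 backtracks) guarantees the objective
does not increase; a failed search skips the *W* step for that round and is
counted as a warning, not an error.

**Scaling of λ.** The user-facing weight is dimensionless:
λ = λ̃ · D(X | W₀H₀) / log det(W₀ᵀW₀ + δI) at the initialization, making λ̃
comparable across cohort sizes and burdens. λ̃ is tuned by running mvNMF over
a logarithmic grid (default 10⁻¹⁰ … 2) and keeping the largest value whose
sample-wise reconstruction errors are not significantly worse than those of
the near-unregularized smallest value — "worse" meaning either a one-sided
Mann–Whitney U test or a tail test rejects at 0.05. The tail test is this
package's own construction: pool both samples, take the pooled 90th
percentile, and compare exceedance counts by a one-sided Fisher exact test
(`sigdecon.stats.tail_test`); it targets a handful of exceptionally bad
samples that barely move rank statistics. Tuning degenerates by design when
the model can fit exactly (p = r: every λ̃ > 0 is "significantly worse" than
a perfect fit), so demonstration fixtures on 3-channel data fix λ̃ = 0.01, a
mid-grid value representative of what tuning returns on realistic cohorts.

**Convergence and numerics.** Relative objective change below `tol`
(default 1e-8) or `max_iter` (default 10 000); divisions and logs are
protected at 1e-16. Discovery runs on column-normalized input by default so
that hypermutated samples cannot dominate the objective; refitting always
uses raw counts so exposures carry absolute burdens.

## Selecting the number of signatures

For each candidate rank *r*: tune λ̃ once, run `n_rep` (default 20) mvNMF
replicates from different initializations, drop replicates whose
reconstruction error exceeds the median by more than five median absolute
deviations, and pool the surviving signature columns. The pooled spectra are
clustered and the number of clusters *k* is chosen by the gap statistic —
crucially *k* is free to disagree with *r*. At the true rank, replicates
rediscover the same *r* spectra (*k = r*, tight clusters); over-specified
runs produce split or ghost signatures (*k ≠ r* or ragged clusters). The
selected rank is the largest *r* with *k = r*, mean silhouette ≥ 0.7 and
minimum per-cluster silhouette ≥ 0.2 (cosine distance); the silhouette gates
catch accidental *k = r* coincidences. Consensus signatures are cluster
means; consensus exposures are recomputed by NNLS.

**Gap statistic.** Within-cluster dispersion W_k is the k-means objective
(inertia; 10 restarts, seeded), the canonical choice for the statistic, and
the null is uniform sampling in the per-dimension bounding box
(default 50 draws); we return the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}. Two guards address a degeneracy specific to
replicate clustering: points that are numerically coincident overall
short-circuit to k = 1, and W_k is floored at 10⁻³ · W₁ so that
machine-precision-tight clusters register as "perfect" rather than endlessly
improvable — without the floor the log dispersion of such clusters keeps
falling under further splits and the standard-error rule never fires.
Hierarchical clustering (average linkage, cosine distance) is used for the
consensus means and silhouettes, where dendrogram cuts are the field's
convention.

## Matching and refitting: likelihood-based sparse NNLS

Fitting a sample x against signatures W by plain NNLS
(min_{h≥0} ‖x − Wh‖₂²) over-assigns: many signatures receive small spurious
exposures. We refine the NNLS solution by bidirectional stepwise selection
under the multinomial log likelihood

    log L(h | x) = Σᵢ xᵢ log wᵢ,   w = Wh / ‖Wh‖₁,

divided by Σᵢ xᵢ (per-mutation units, so the threshold ε is independent of
burden). Backward: tentatively drop each active signature (NNLS on the
reduced support), drop the cheapest if its cost < ε. Forward: tentatively add
each inactive signature, add the best if its gain > ε. Alternate until a full
pass changes nothing; the same ε in both directions prevents add/remove
cycles. Equal tie-breaks go to the lowest column index. The procedure is a
greedy coordinate ascent of log L − ε·|support|; it matches exhaustive
enumeration on identifiable instances but can land in a different local
optimum when the catalog contains near-duplicate directions — one reason the
thresholds are optimized in silico rather than trusted blindly.

Because the per-mutation log likelihood equals −KL(x̂ ‖ w) minus the entropy
of x̂ = x/‖x‖₁, probability vectors are legitimate inputs: **matching** a de
novo signature to a catalog is the same algorithm applied to x̂, with weights
reported normalized over the support. A **thresholded NNLS** baseline (zero
signatures below a relative-exposure cutoff, then re-fit) is provided for
comparison; on cohorts containing flat signatures its precision–recall
behavior is strictly worse, because spurious flat exposures routinely exceed
small true ones.

**Background cleaning.** After matching, a matched signature is treated as an
over-fit to background and removed iff (1) the sum of its own probabilities
over channels where its weighted contribution reaches at least 1% of the
unit-mass reconstruction is below 15%, and (2) its peak weighted contribution
is more than 5× below the de novo spectrum's peak probability. We read
"contributes at least 1%" in absolute probability units of the
reconstruction: a flat signature at small weight then has an empty active set
and is removed, which is the case the rule exists for, whereas measuring
contribution relative to the reconstructed value per channel would mark every
background channel active and neuter the rule. A genuinely flat de novo
spectrum is protected by condition (2). The alternative "own-mass" reading
(channels where the signature's own probability ≥ 1%) is available behind a
switch for comparison.

## In silico validation and threshold optimization

Given final assignments (W_s, H_s), simulate X_simul by per-sample
multinomial draws from W_s H_s (burden = rounded reconstructed total), rerun
discovery on X_simul with the original settings (same r, λ̃, replicate
count; seeds derived deterministically from a master seed), and pair the
rediscovered W_simul with the original W_data one-to-one by the Hungarian
algorithm on cosine distance. The mean paired cosine distance measures how
consistent the assignment is with the data. Discrepancies localize through
the over/under-assignment profile: each paired de novo signature (data and
simulation side) is decomposed by NNLS onto the assigned signatures and the
positive (excess in simulation = over-assignment) and negative (excess in
data = under-assignment) weight differences are accumulated per assigned
signature.

The matching and refitting thresholds are optimized by grid search under this
same score: the minimizing pair anchors a candidate set, expanded by every
pair whose element-wise L1 errors (per-channel differences over paired
signatures) are not significantly larger (Mann–Whitney AND tail test both
p > 0.05); among candidates the fewest assigned signatures wins, then the
largest thresholds. A sequential mode first optimizes the matching threshold
with the refitting threshold pinned at 10⁻⁴, then the refitting threshold.

## Preprocessing

**Gini outlier removal.** After an initial discovery, each signature whose
relative per-sample exposures have Gini coefficient above 0.65 is flagged;
its samples are visited in descending relative exposure and removed while
each removal lowers that signature's Gini by more than 0.05 (one pass per
flagged signature, signatures processed in index order). Relative (column-
normalized) exposures are used for both the ranking and the Gini itself, for
scale invariance. **Stratification.** Samples are L1-normalized and clustered
hierarchically on cosine distance with k chosen by the gap statistic
(k = 1 is a legitimate outcome); clustering the exposures from an initial
discovery is recommended over raw counts.

## Synthetic data

Cohorts are Dirichlet-multinomial: per sample, relative exposures ~ symmetric
Dirichlet(α = 0.1) — a concentration representative of real per-tumor
exposure sparsity — burden ~ Poisson(5 000), counts ~ multinomial over the
composite spectrum. Optional distortions: zeroing relative exposures below
0.01, multiplicative Gaussian count noise at 1–10%, and spike-in of an
artifact spectrum at 5% of each sample's burden. Planted signatures are
drawn as sparse Dirichlet spectra subject to a pairwise cosine-distance
floor, optionally blended with a flat component to mimic the flat signatures
(SBS3/SBS5/SBS40-like) that make separation hard.

What this emulates well: burden heterogeneity, sampling noise, exposure
sparsity, flat-signature confusability. What it does not: correlated channel
noise from sequencing artifacts, tumor-type-specific exposure correlation
structure, mis-specified channel opportunity (genome vs exome), subclonal
mixtures. Passing benchmarks therefore demonstrate algorithmic correctness
and the claimed qualitative orderings, not field performance on any
particular cancer cohort.

## Problem sizes and tolerances used in tests and the acceptance script

Discovery-level checks run at the reference conditions (n = 200 samples,
burden 5 000, α = 0.1). Rank-selection checks use 10 replicates per rank, a
4-point λ̃ grid (10⁻¹⁰, 10⁻³, 10⁻², 0.1), convergence tolerance 10⁻⁷ with at
most 2 000 iterations, and 30 gap-statistic reference draws; refitting sweeps
use 10-point threshold grids and cohorts of 40–60 samples; validation reruns
use 4 discovery replicates. These sizes are the package's chosen desk-scale
defaults for its own verification; the library defaults remain the reference
values stated above.

## Known limitations

- Stepwise selection is greedy; with near-duplicate catalog entries the
  recovered support can differ from the global penalized-likelihood optimum.
- λ̃ tuning is meaningless when an exact factorization exists (p ≤ r) and
  conservative on very clean data, where any regularization measurably
  perturbs an otherwise near-perfect fit.
- The gap-statistic dispersion floor (10⁻³ · W₁) is a pragmatic guard; data
  whose genuine cluster spread sits near that ratio could be mis-read as
  degenerate.
- Exposure uncertainty (bootstrap confidence intervals, per-sample p-values)
  is out of scope, as are raw VCF/MAF-to-channel counting and
  opportunity renormalization.
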
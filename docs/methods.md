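# Methods

## The contrast-feature template

The package's central object is a *ratio template*: a set of named
facial regions with an ordered list of twelve ordinal luminance
conditions, each asserting that one region is brighter than another.
Scoring an image takes the arithmetic mean luminance of each region
(images live on a [0,1] luminance scale; 8-bit files are divided by 255
on read), forms the twelve signed differences ("feature strengths"),
counts the strictly positive ones (the correct-feature count, CF), and
averages them (mean strength). Exact ties count as *not met* with
strength zero — "correct direction" means strictly positive. Because
only signs and differences of region means enter, CF is invariant to
adding a constant luminance everywhere, and strengths scale linearly
with luminance scaling.

The original template's geometry exists only as a figure, so the
default template defines eight axis-aligned, pairwise disjoint
rectangles (forehead, left/right eye, nose, left/right cheek, mouth,
chin) on a 100×100 canvas, with a **bipartite** condition set:
forehead, cheeks, nose and chin appear only on the brighter side, eyes
and mouth only on the darker side (forehead>eyes, cheeks>eyes,
nose>eyes, cheeks>mouth, nose>mouth, forehead>mouth, chin>eyes). This
is the classic ratio-template pattern for frontal faces; the geometry
and the condition list are both user-overridable through a YAML/JSON
template file (0-based, row-major, half-open rectangles), and all
downstream code works for arbitrary acyclic condition sets. Whether the
original scoring aggregated regions by mean or some other statistic is
not recorded; the mean is assumed throughout.

## Synthetic stimuli

Stimuli are rendered by painting each region at a chosen luminance on a
uniform background (default 0.5), adding i.i.d. Gaussian pixel noise
(default sd 0.05 — enough to avoid flat images, small enough that
region means, averaged over hundreds of pixels, keep CF stable) and
clipping to [0,1].

The exact-k generator inverts the CF categorization by rejection
sampling over region luminances. A plain uniform proposal is slow in
the tails (k near 0 or 12), so proposals blend a uniform draw with the
template's ideal assignment (or its luminance inversion) by a random
weight; acceptance requires exactly k strictly positive assignment-level
strengths, every |strength| above a 0.005 margin, and an identical
re-score of the rendered noisy image. The margin is a deliberate
strengthening: it keeps the CF count stable under 8-bit quantization
round-trips, so a stimulus re-read from PNG re-scores identically. The
"ideal assignment" is computed for any acyclic condition digraph by
longest-path layering, which makes the generator correct for arbitrary
user templates. Under the default template all thirteen k values
generate in well under a second.

The stimulus complement mirrors the experimental design: 5 training
targets (CF 11–12), 5 training distractors (CF 6), 10 test targets
(five at CF 6, five at CF 12) and 15 test distractors (five per nominal
group CF 1 / 6 / 12, the middle and top groups tolerating 5–6 and
11–12 respectively). Within each category a pool of candidates
(3 extra per group) is thinned by greedy maximin selection on *pixel
dissimilarity* — root-sum-squared pixel difference divided by the
square root of the pixel count, a scaled Euclidean distance and hence a
metric — favouring mutually dissimilar exemplars, deterministically
(lowest-index tie-break). What the generator does **not** emulate:
photographic texture, natural-image backgrounds, or any within-category
structure beyond region luminances and pixel noise. Tests passing on
these stimuli show that the scoring, simulation and analysis machinery
is correct, not that real faces or natural non-faces behave this way.

## Behavioral simulation

Choices follow a standard 2AFC psychometric model with lapse λ: on a
new pair with feature-strength difference Δ (target minus distractor
mean strength), P(correct) = λ/2 + (1−λ)·logistic(kΔ) with sensitivity
k; trained pairs use a fixed asymptote p_old under the same lapse,
P = λ/2 + (1−λ)·p_old, so λ = 1 forces chance everywhere. An optional
side bias shifts the choice on the logit scale; it defaults to zero.
Defaults k = 4, λ = 0.25, p_old = 0.95 put trained-pair accuracy at
0.8375 — comfortably above the 80% criterion so training converges —
while new-pair generalization stays lapse-limited and graded in Δ.

Training runs five cumulative phases (phase p presents all pairs among
the first p targets and distractors, order reversed for the second half
of the cohort); sessions contain 100 non-correction trials; after each
error the same pair and side repeat as flagged *correction trials*
until answered correctly (the repetition rule is our choice; only the
trials' purpose, discouraging side bias, is documented). A phase
advances at ≥80% session accuracy for two consecutive sessions
(relaxed variant: ≥75% for four); non-convergent models hit a
configurable session cap and raise a truncation error. Testing runs
two rounds of three blocks, each block containing one 100-trial session
per protocol (protocols pair all test targets with the distractor
groups {1,6}, {1,12}, {6,12}; order rotates across animals). A third
of test trials present trained pairs with real reward; the rest present
new pairs rewarded with probability 0.8 independent of the choice.
Correction trials are simulated during training only — under random
reward a correction contingency has no defined "correct" feedback — and
are excluded from every accuracy statistic downstream regardless.

`recover_parameters` refits (k, λ) from new-pair trial logs by L-BFGS-B
maximum likelihood from several starts (bounds k ∈ [0, 200],
λ ∈ [0, 0.999]), warning when estimates land on a boundary; with k = 0
the lapse is structurally unidentifiable and boundary estimates are
expected.

## Analysis

All accuracy statistics pool animals and exclude correction trials.
Learning curves average per-rat session accuracy within phase, with
across-rat standard errors. Condition accuracies use the exact
two-sided binomial test against 0.5 (summing outcomes whose pmf does
not exceed the observed one) and Clopper–Pearson 95% intervals — the
original report names only "binomial test", so the exact forms are our
choice. The pairwise matrix holds 100×correct/total per test pair
(NaN where untested); pooling across rounds is exact: the pooled cell
is the trial-count-weighted mean of the per-round cells. Split-half
reliability correlates the round-1 and round-2 matrices and is
corrected to full length by Spearman–Brown, 2r/(1+r).

The permutation test shuffles the behavior matrix's defined cells as
one flat vector — no row/column structure is preserved, matching a
description of permuting "the matrix" without constraints — and
recomputes the Pearson correlation against the fixed model each time;
p = #{null r ≥ observed}/n_perm with no +1 smoothing. For any fixed
non-constant grids the permutation null has mean 0 and variance exactly
1/(n−1); with the full 150-cell grid, σ = 1/√149 ≈ 0.082. Two-sample
comparisons use the pooled-variance t-test (df = n₁+n₂−2).

## Layer readouts and noise matching

Activation providers expose `layer_names` and `activate(images, layer)`
and must be deterministic. Two are bundled: a raw-pixel identity
provider, and a seeded random-weight convolutional hierarchy with the
standard 13 block names (conv1, norm1, pool1, conv2, norm2, pool2,
conv3–5, pool5, fc6–8) — convolution, local response normalization and
2×2 max pooling in numpy, pre-rectification responses exposed for conv
and fc blocks. An adapter to a pretrained network is just another
object satisfying the same protocol; none is required.

The readout is a hinge-loss linear SVM fit to the 10 training stimuli.
The box constraint is `regularization / n_samples` (default 10/n), so
the objective is ridge plus *mean* hinge loss — duplicating the
training set leaves the rule exactly unchanged. Scores are signed
distances to the hyperplane, positive on the target side; a pair is
correct when the target-minus-distractor score difference is positive
(ties count as incorrect).

Trial noise is zero-mean Gaussian on the representation with a fresh
draw per simulated trial. For a linear rule such noise projects onto
the signed distance as N(0, σ²), so the simulator draws the scalar
projection directly — distribution-identical to perturbing the
activation vector, and orders of magnitude cheaper. Calibration
bisects σ until mean training-pair accuracy (over all 25 target ×
distractor training pairs, default 4000 Monte-Carlo draws per pair) is
within tolerance (default 0.01) of the target (default 0.80,
user-overridable); targets above the noiseless accuracy raise. Per-layer
test accuracy gets a 95% CI from leave-one-pair-out jackknife standard
errors (the resampling unit is the test pair). Layer score-difference
grids are correlated with the behavioral matrix and the
feature-strength model; the behavioral correlation is also reported
normalized by the Spearman–Brown-corrected reliability.

## Pipeline, determinism, and problem sizes

`run_pipeline` chains stimuli → behavior → analysis → readout, derives
one sub-seed per stage from the master seed via `SeedSequence.spawn`,
and writes a manifest of config, stage seeds and SHA-256 hashes of
every output; reruns are byte-identical. Default sizes follow the
experimental design (8 animals, 100-trial sessions, 2 rounds × 3 blocks
× 3 protocols, 1000 permutations); the test suite and the acceptance
script use the same structure with cohorts of 2–8 simulated animals,
which the analyses' pooled trial counts (hundreds per condition) make
ample for the direction-level and null-distribution checks they assert.

## Known limitations

* The default region geometry and condition list are a faithful
  *pattern* for a frontal-face ratio template, not a transcription of
  any particular published figure; users with the original template
  should supply it as a template file.
* The decision model is a generative stand-in: a logistic link in mean
  feature-strength difference with a symmetric lapse. Real animals show
  history effects, drifting biases and stimulus-specific strategies the
  simulator does not attempt.
* The bundled convolutional hierarchy has random weights; it provides a
  deterministic, realistically structured 13-block representation for
  exercising the readout machinery, not a model of a trained network's
  features.
* Pixel dissimilarity is computed on raw luminances; no frequency
  weighting or acuity modeling is applied.
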
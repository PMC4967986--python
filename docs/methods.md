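# Methods

This note documents the models and procedures implemented in
`roundlvq`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## The LVQ family

All variants maintain a codebook of m labeled prototype vectors
initialized by sampling training rows without replacement, with
per-class counts proportional to class frequencies (largest-remainder
allocation, at least one prototype per class). One *iteration* is one
single-sample presentation; the presentation schedule is a seeded
shuffle of the training rows, cycled, so a run is bit-reproducible from
(data, config, seed). The learning rate decays linearly,
α(t) = α₀(1 − t/T).

Defaults — α₀ = 0.3, m = 40 codebook vectors, T = 2000 presentations,
70/30 percentage split, R = 50 randomizations — are the configuration
the underlying study found to work best for its brain-image data; the
desk-scale tests use scaled-down m and R, noted per test.

* **LVQ1** moves the winner toward a same-class input and away from a
  different-class input: w ← w ± α(x − w).
* **LVQ3** updates the winner and runner-up when the input falls in the
  window min(dᵢ/dⱼ, dⱼ/dᵢ) > (1 − w)/(1 + w) (w = 0.3 by default,
  threshold ≈ 0.538) and exactly one of the two matches the class:
  the matching prototype attracts, the other repels. When **both**
  match, both attract with the damped rate εα (ε = 0.3). The
  both-match update is applied without the window condition; the window
  gates only the attract/repel case. With rounded distances a tie
  dᵢ = dⱼ counts as inside the window (ratio 1).
* **OLVQ1/OLVQ3** give every prototype its own learning rate, updated
  by the optimized recursion α ← α/(1 + sα) with s = +1 after a correct
  win and s = −1 after a wrong one, capped at α₀. Both neighbor updates
  in OLVQ3 use the winner's rate; only the winner's rate is updated.
* **Multipass LVQ** runs OLVQ1 at α₀ = 0.3 for 40·m presentations
  (the midpoint of the recommended 30–50·m), then LVQ3 at α₀ = 0.05
  for 10× as long, warm-started from the pass-1 codebook. A pass-2
  rate ≥ 0.1 triggers a warning (the pass is meant to fine-tune
  slowly), not an error. Both pass lengths are recorded in the model's
  training trace.
* **Hierarchical LVQ** trains a small level-1 LVQ1 codebook
  (2 × number of classes by default) that partitions the training set
  by winner; points whose runner-up distance is within (1 + overlap)
  of the winner distance (overlap = 0.1) join both partitions, so
  neighboring sub-models share their border region. Each multi-class
  partition trains an LVQ1 sub-model over its own classes;
  single-class partitions become leaves. Empty partitions are dropped
  and routing falls back to the nearest remaining level-1 prototype.

The update equations above are the standard Kohonen forms; the method's
specific contribution is the winner-selection rule, not the updates.

### Rounded winner selection

`round_distance` rounds the Euclidean distance half-away-from-zero to
`round_decimals` places (0 by default, i.e. to the nearest integer).
Rounding granularity interacts with feature scale, which is why the
decimals are configurable and why the training workflow min-max
normalizes features by default. A `rounded_squared` mode (round the
squared distance, no square root) is exposed for fidelity testing
against formulations that omit the root.

Training tie-breaks are uniform among tied prototypes via the run's
seeded generator — the mechanism that keeps marginal prototypes in the
competition. Inference uses lowest-unrounded-distance-then-lowest-index
so that predictions are a pure function of the model and the input.
Whether rounding should apply at inference as well as training is not
settled by the source method; both phases use the configured mode here,
and `distance_mode="euclidean"` restores classical behavior everywhere.

## Multirandomization

Each run r derives its seed from (meta_seed, r) through a
splitmix64-style mixer (kept below 2³¹), shuffles the dataset with it,
takes the first ⌊0.7·n⌋ rows as training data (the split is positional;
shuffling is the only randomness), fits, and scores on the remainder.
The best model by held-out accuracy is retained; ties go to the lowest
run index. The reported standard deviation uses the sample (n − 1)
denominator.

Selection scores on the same held-out split that is reported — there is
no inner validation split. That is the protocol as defined; its
selected accuracy is an optimistic estimate, which users should treat
as a model-selection score rather than an unbiased error estimate.

The reported `rmse_indicator` is √(1 − accuracy), the root mean squared
0/1 misclassification indicator — the reading under which a ~90%
accuracy pairs with an error of ~0.31. It is exposed alongside accuracy
rather than replacing it.

## Imaging pipeline

Stage order: high-pass filter → additive enhancement → 3×3 median →
(band region growing ∥ mixture thresholding) → mask combination →
6×6 opening → subtraction.

* **High-pass.** The transfer function is built on a centered frequency
  grid (radius d̂ = √(u² + v²)) and shifted to the FFT layout; the real
  part is taken after inversion; no padding. Ideal: 0 for d̂ ≤ d, 1
  beyond. Butterworth: 1/(1 + (c·d/d̂)^2k), zero at the DC bin.
  Exponential: exp(−a(d/d̂)^k), zero at DC. Scale constants default to
  c = 1 and a = 1 (√2 − 1 and ln 2 are the standard half-power
  alternatives, available in the spec object). The default is
  Butterworth, order 2, cutoff 30 grid units on 128×128 inputs: a high
  cutoff keeps the filter's spatial response narrow, so the step
  response at the head boundary is a thin over/undershoot ring that the
  median stage removes instead of a broad ringing halo that would leak
  into the segmentation band. The filter output is left unclamped;
  enhancement (source + detail + c, c = 25) clamps to [0, 255].
* **Median filter** uses edge replication at the borders.
* **Region growing** realizes grow-from-every-unclaimed-seed as
  connected-component labeling (8-connectivity by default) of the
  strict band (80, 90). The band is a fixed property of the method;
  on other data it must be re-tuned.
* **Mixture thresholding.** A 1-D Gaussian mixture is fitted to the
  256-bin intensity histogram by weighted EM (tolerance 1e-6 on the
  mean log-likelihood, ≤ 500 steps, variances floored at 1e-6 with a
  warning). EM runs from two deterministic starts — means at the d mass
  quantiles, and means spread evenly over the value range — and keeps
  the higher-likelihood fit; the second start is what finds a bright
  lesion mode that holds only ~2% of the pixels, which quantile
  initialization never sees. A least-squares fit of the mixture
  density to the normalized histogram (`fit_mode="mse"`) is available
  as the alternative. Thresholds between adjacent modes are the
  crossings of the weighted densities (minimum-error boundaries), found
  by bisection to 1e-6, with a midpoint fallback (and warning) when the
  densities do not cross between the means. The pipeline fits **three**
  modes (background, tissue, bright lesion) and keeps pixels above the
  top threshold; the standalone fitting function defaults to two modes
  (object/background), which is the usual bimodal-histogram use.
* **Mask combination** is the union of the two branches by default
  (the permissive reading; intersection is a config option).
* **Subtraction.** The "opened image" handed to the subtraction stage
  is the source with the opened segmentation removed; subtracting it
  from the source (the default `src_minus_opened` direction, negatives
  clamped to 0) therefore isolates the segmented structure as a bright
  remnant on black — the form the texture stage consumes. The raw
  pixelwise operation with either direction is available as
  `imaging.subtract`.

## Texture features and PCA

Co-occurrence matrices use 8 uniform quantization levels over [0, 255],
offset distance 1, and the four offsets (0, Δ), (−Δ, Δ), (−Δ, 0),
(−Δ, −Δ) for 0°/45°/90°/135° with rows increasing downward and the
origin top-left. Symmetric counting (pair + reversed pair) is the
default, so two horizontally adjacent equal pixels contribute 2 to the
0° matrix. The 13 classical Haralick descriptors are computed per
normalized matrix with log base 2 and 0·log 0 = 0; sum variance is
taken about the sum average; correlation and the information measures
return 0 on degenerate (zero-variance / zero-entropy) matrices. The
feature vector averages the descriptors over the four angles (a degree
of rotational invariance) for the source image and the pipeline's final
image, concatenated to 26 features; eight first-order statistics of the
segmented image can be appended. PCA (top-q eigenvectors of the sample
covariance, q = 4, sign fixed by making the largest-magnitude loading
positive) is fitted on the training split only inside the evaluation
loop, never on the full dataset, to avoid leakage.

## Synthetic generators

Phantoms are 128×128 images: background mean 8, elliptical head
(semi-axes 0.42/0.34 of the image) mean 45, optional lesion disk mean
85, i.i.d. Gaussian noise σ = 2, clamped to [0, 255]. The lesion mean
and noise level are chosen so that ≈95% of lesion pixels fall inside
the (80, 90) region-growing band — planted lesions are detectable *by
construction*. The generators emulate geometry, contrast and additive
noise only: no bias fields, Rician noise, T1/T2 contrast physics, or
anatomical texture. Passing tests therefore demonstrate correctness of
the pipeline's mechanics and the classifier's behavior under the stated
contrasts, not clinical performance on real MRI.

Blob tables draw isotropic Gaussians at configurable centers (default:
centers 6σ apart, where nearest-centroid accuracy is effectively 1);
the overlapping-class stability tests move the centers 2σ apart.

## Problem sizes in tests

The desk-scale test suite uses 2-class blobs with n = 200 and m = 4
prototypes (2000 presentations), 60 phantoms with R = 10 randomizations
and 3 protocol seeds for the end-to-end check, 20 phantoms for
segmentation recovery, and 10⁴ draws for mixture recovery. These sizes
were chosen as the smallest at which the properties under test are
stable across seeds.

## Known limitations

* The (80, 90) band, enhancement constant 25, and 6×6 element are
  fixed method constants tuned for a specific acquisition; the phantom
  generator was designed around them rather than the reverse.
* Best-model selection without an inner validation split inflates the
  selected accuracy (see above).
* The hierarchical variant is a concrete two-level realization of a
  loosely specified architecture; its knobs (level-1 codebook size,
  overlap) are exposed rather than canonical.
* EM mixture fitting on images operates on the 256-bin histogram, which
  is exact for 8-bit data but bins sub-integer structure.
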
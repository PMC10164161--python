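# Methods

`clockfactors` implements a semi-supervised analysis of clock drawing
test (CDT) images: a generative latent-variable model learns the
constructional factors of clock drawings from unlabeled data, the
factors are examined statistically for group differences between
dementia and control drawings, and the encoder is fine-tuned with a
small supervised head to classify the two groups.  This note documents
the models, their assumptions, the defaults, and what the synthetic
data can and cannot establish.

## 1. Synthetic clock generator

Clinical CDT images of the kind this pipeline targets are not publicly
distributable, so the package ships a generator that renders clock
drawings from an explicit ten-dimensional factor vector:

| factor | support | ideal | meaning |
|---|---|---|---|
| `size` | 0.2–1.0 | 0.8 | face diameter / canvas |
| `obovate` | −1..1 | 0 | egg ("avocado") asymmetry along the vertical axis |
| `prolate_oblate` | −1..1 | 0 | tall (−) vs flat (+) face |
| `ellipse_tilt` | −1..1 | 0 | signed orientation of elliptical eccentricity |
| `hand_vshift` | −0.5..0.5 | 0 | vertical offset of the hand pivot (fraction of radius) |
| `hand_angle` | 30–180° | 90° | inter-hand angle ("ten after eleven" = 90°) |
| `face_squareness` | −1..1 | 0 | square ↔ circle ↔ rhombus morph |
| `side_bulge` | −1..1 | 0 | localized left/right rim bulge |
| `hand_rotation` | −60..60° | 0° | rigid rotation of the hand assembly |
| `digit_dropout` | 0..1 | 0 | fraction of the 12 dial digits omitted |

The face contour is a polar curve: an anisotropic ellipse carrying the
prolate/oblate term, multiplied by low-order harmonics for tilt
(cos 2θ about 45°), obovateness (sin θ), squareness (cos 4θ) and a
localized Gaussian bulge.  Low-order harmonics keep the contour closed
and simple over the entire factor range.  Hands aim at the 11 and 2
dial positions before rotation; digits are text glyphs at canvases
≥ 96 px and filled discs below that (resizing to 64×64 destroys glyph
detail either way, so nothing downstream depends on glyph shape).
Drawings are rendered at 256 px and pushed through the same
preprocessing as any external page image, so the 64×64 standardization
is exercised rather than bypassed.

Cohort sampling draws each factor independently from a truncated
Gaussian centered at the ideal clock (controls) or at the ideal plus a
per-factor effect shift (dementia).  The default shifts follow the
clinical pattern the analysis is designed to detect — smaller,
avocado-shaped, oblate faces with upward-shifted, widened,
anticlockwise-rotated hands — with `size` carrying the strongest
standardized effect.  Demographics are group-conditional
Gaussians/Bernoullis (dementia ≈ 80 ± 6 years, 13 ± 3 education years,
32 % female, 98 % white; controls ≈ 68 ± 6, 16 ± 2, 46 %, 95 %), which
deliberately confounds age and education with the label.  Labeled
splits default to 84:263 fine-tuning and 28:87 test clocks; each
person contributes one command and one copy drawing sharing
demographics, and every clock is one sample.

What the generator does *not* emulate: stroke order and pen dynamics,
handwriting variability in digit glyphs, perseveration and other
discrete semantic errors, and within-subject correlation beyond shared
demographics.  Passing tests on synthetic cohorts therefore
demonstrate that the pipeline recovers and exploits *geometric*
construction factors planted in the images — not that it would reach
the same performance on clinical drawings.

## 2. Preprocessing

A page is Otsu-thresholded; the largest connected ink component
(subject to a minimum area fraction, default 1e-4 of the page) is
cropped to its tight bounding box, padded with white to a square
(short axis symmetric, odd pixel after), and downscaled to 64×64 by
area averaging (PIL `BOX` kernel).  Area averaging is deliberate:
stroke ink is conserved proportionally, so a larger original drawing
ends up with fainter strokes at 64×64, and total ink mass becomes a
monotone proxy for original size — the signal the size latent factor
uses.  Images are stored white = 1; the model consumes the ink-bright
complement so Bernoulli reconstruction targets sparse positives.  No
binarization is applied after resizing.

## 3. Relevance-factor VAE

The model is a VAE with D = 10 diagonal-Gaussian latent dimensions and
two additions: a total-correlation (TC) penalty and per-dimension
relevance gates.

**Objective.**  For a batch x with posterior q(z|x) = N(μ, diag σ²),
reparameterized sample z = μ + σ·ε, decoder Bernoulli probabilities
x̂, and gates r = sigmoid(ρ) ∈ (0,1)^D:

    L = CE(x, x̂) + Σ_d KL_d + γ · r̄ · TC(r ⊙ z)
        + λ Σ_d r_d + η Σ_d (1 − r_d) · KL_d

where KL_d = ½(μ_d² + σ_d² − 1 − log σ_d²) is the per-dimension prior
KL, CE the pixel-sum cross-entropy, and r̄ the mean gate.  The TC term
pushes the aggregate posterior toward independence on the *gated*
subspace; with all gates closed it vanishes identically.  The gate
terms implement relevance: the sparsity term λΣr pulls gates closed,
the coupling term η Σ(1−r)KL holds a gate open exactly when its
dimension's prior KL exceeds λ/η, and — once a gate has closed —
actively shrinks that dimension's KL, migrating its residual
information into the open dimensions.  A dimension ends up flagged
nuisance (r ≈ 0) when its divergence from the prior does not justify
the sparsity cost; relevant dimensions keep large KL without penalty.
Defaults: γ = 6.4, λ = 1.8, η = 1.0, chosen so the gate threshold λ/η
sits below the per-dimension KL of an information-carrying dimension
(2–4 nats on synthetic clocks) and above the KL of a redundant one.

**TC estimation.**  Default is the adversarial density-ratio
estimator: a small MLP discriminator is trained concurrently (logistic
loss, Adam, lr 1e-4, β = (0.5, 0.9)) to distinguish joint latent
samples from dimension-permuted ones; its mean logit on joint samples
estimates KL(q(z) ‖ ∏ q(z_d)).  A closed-form Gaussian surrogate
(−½ log det corr(z), exact for Gaussian codes, deterministic and
cheaper) is available via `tc_estimator="gaussian"` for CPU-bound
runs; its gradient is computed analytically through the correlation
matrix.

**Architecture.**  Encoder 4096 → 256 → 128 → 2D and a mirrored
decoder (ReLU, linear heads; the encoder output layer is
zero-initialized so the untrained posterior equals the prior).  The
usual implementation of this model family uses a convolutional
encoder on a GPU; a fully-connected network was chosen here because
the whole stack (forward, backward, Adam) is hand-written in float64
numpy — gradients are finite-difference-checked in the test suite —
and an MLP of this size trains in minutes on one CPU core while still
recovering the planted factors.  Network weights ride Adam at
lr 1e-3 for desk-scale runs (the full-scale 1e-4/1400-epoch schedule is
available via `TrainConfig.full_scale()`); the gate parameters ρ ride a
faster Adam (lr 1e-2) because a gate must travel several logit units
within a desk-scale run.

**Seeding.**  One master seed fans out to data order, initialization,
reparameterization noise and permutation streams; identical config +
data give bit-identical parameters.

**Downstream features** are posterior means, not samples, so analysis
tables and classifier inputs are deterministic given the model.

## 4. Latent-space analysis

* **Traversals**: decode a sweep of one latent coordinate over
  [−3, +3] (7 steps), others fixed at 0 — the prior mean, whose decode
  is the model's prototype clock.
* **Propensity matching**: logistic propensity score on age and
  education (standardized), greedy 1:k nearest-neighbor matching
  without replacement in descending case-score order, no caliper by
  default (exposed in the API).  Standardized mean differences are
  reported before/after.  With the default labeled cohort and k = 2
  this yields the cases + 2·cases analysis set.
* **Group comparison**: per-dimension Welch (unequal-variance,
  two-tailed) t-tests via `scipy.stats.ttest_ind(equal_var=False)`,
  Benjamini–Hochberg step-up across the D dimensions at q = 0.01
  (statsmodels `fdr_bh`); raw and adjusted p both reported.
  A dimension with zero variance in both groups is reported at
  t = 0, p = 1 and flagged degenerate.
* **Atypical occurrences**: count of dementia samples strictly more
  than k = 2 control SDs from the control mean, per dimension.
* **Correlation network**: Pearson matrix over the D latents plus the
  0/1 label (point-biserial); edges where |r| > 0.2 with sign;
  subnetworks are connected components (≥ 2 nodes) of the
  positive-edge graph excluding the label node.  Constant columns are
  dropped with a warning.

## 5. Classifier

The pretrained encoder (deep-copied, so the unsupervised model is
never mutated) is fine-tuned jointly with a feed-forward head by
weighted binary cross-entropy (positive class × 3.125, offsetting the
263:84 imbalance), Adam, lr 0.0075, 20 epochs.  Three feature modes
share one evaluation code path: latents only (head [7, 4], batch 32),
latents + demographics (head [512, 256, 128], batch 8), demographics
only (same large head).  Demographics enter as fine-tuning-set
standardized age and education plus 0/1 indicators for sex (F = 1) and
race (white = 1).  Metrics: AUC by the Mann–Whitney rank statistic
with tie averaging; sensitivity, specificity, precision, NPV, accuracy
and F1 at threshold 0.5 (no operating-point optimization); F1 with a
zero denominator is defined as 0.  Confidence intervals: B = 100
bootstrap resamples of the test rows, median and 2.5/97.5 percentiles
per metric; resamples lacking a class skip AUC and are counted, not
dropped.  Hyperparameter selection uses stratified 5-fold CV on the
fine-tuning set maximizing mean fold AUC, ties broken toward the
smaller head.

## 6. Numerical choices and degenerate inputs

* Bernoulli probabilities are clipped to [1e-7, 1 − 1e-7]; log-variances
  to [−12, 12].
* The encoder head's zero initialization makes the untrained model's
  posterior exactly the prior (KL = 0 at step 0).
* Odd padding puts the extra pixel after the content; ties in AUC rank
  averaging follow the standard midrank convention.
* Blank pages, empty crops, single-class labeled sets, zero-variance
  dimensions and undersized batches raise explicit errors (or flagged
  degenerate rows where the contract asks for them).

## 7. Problem sizes

Desk-scale defaults (used by the tests and the acceptance script) are
chosen to keep a full run in the minutes range on one CPU core:
2,000 unlabeled clocks and 100 epochs for the factor-recovery
experiment and for the cohort study's unsupervised stage (the CLI
pipeline default is a lighter 400-clock split), plus the 84/263 +
28/87 labeled splits; B = 100 bootstrap; 200 outer
replications for the interval-coverage experiment.  The full-scale
protocol (23,521 clocks, 1400 epochs) is reachable through the same
configs on bigger hardware.

## 8. Known limitations

* The generator's factors are mutually independent by construction;
  real clock drawings exhibit algorithmically coupled errors, so
  correlation-network structure on real data would reflect genuine
  dependence, not only sampling noise.
* A fully-connected encoder has no translation equivariance; it relies
  on the standardization stage to center content.  Off-center or
  multi-drawing pages outside the extractor's assumptions will degrade
  encodings.
* Factor recovery is assessed by linear correlation against latent
  means; a factor encoded nonlinearly across dimensions counts as
  unrecovered even though a decoder can use it.
* Group statistics can be computed on two feature sources: the RF-VAE
  posterior means, or the cohort's ground-truth factor table (a
  perfectly disentangled reference that isolates the statistics
  pipeline from representation quality).  At desk scale the learned
  representation retains rotational mixing among latents — the
  Gaussian TC surrogate is rotation-blind for Gaussian codes — so a
  "severity composite" latent that sums several shifted factors can
  out-|t| the single size-matched latent even though the size factor
  carries the largest planted standardized shift.  On the factor table
  the size dimension ranks first by |t| and by atypicality count, and
  exactly the shifted factors reach significance.  The size dimension
  on latent features is identified by correlating against controls
  only, because pooling both groups correlates every shifted factor
  with every other through the label.
* The demographics-only classifier inherits the large head of the
  with-demographics mode; with four inputs this is over-parameterized
  and relies on early stopping by epoch count.
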
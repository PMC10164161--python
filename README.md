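# clockfactors

Disentangled latent-factor analysis of clock drawing tests (CDT) for
dementia screening.

The clock drawing test — *"draw the face of a clock, put in all the
numbers, and set the hands to ten after eleven"* — is a standard
cognitive screen: subtle constructional errors (a small face, a
flattened or egg-shaped contour, misplaced hands) track cognitive
decline.  `clockfactors` implements a semi-supervised pipeline that

1. **learns** the constructional factors of clock drawings without
   labels, using a relevance-factor variational autoencoder (RF-VAE),
2. **tests** how those factors differ between dementia and control
   drawings after removing age/education confounding, and
3. **classifies** dementia vs. non-dementia by fine-tuning the encoder
   with a small feed-forward head, reporting bootstrap confidence
   intervals.

Because clinical CDT images are not redistributable, the package ships
a synthetic generator that renders clocks from ten explicit factors
(size, obovateness, prolate/oblate, elliptical tilt, hand vertical
shift, inter-hand angle, squareness, side bulge, hand rotation, digit
dropout) and samples cohorts whose factor and demographic shifts mimic
the clinical pattern.  Ground truth is retained, so the pipeline's
central claim — that the learned latent dimensions align with the true
generative factors — is directly testable.

## The model

For a 64×64 drawing x with posterior q(z|x) = N(μ, diag σ²), D = 10,
decoder Bernoulli probabilities x̂, and relevance gates
r = sigmoid(ρ) ∈ (0,1)^D, training minimizes

```
L = CE(x, x̂) + Σ_d KL_d + γ · r̄ · TC(r ⊙ z) + λ Σ_d r_d + η Σ_d (1 − r_d) KL_d
```

where KL_d = ½(μ_d² + σ_d² − 1 − log σ_d²) is the per-dimension prior
KL, TC(·) = KL(q(z) ‖ ∏_d q(z_d)) is the latent total correlation
(estimated by an adversarial density-ratio discriminator on
dimension-permuted samples, or by a closed-form Gaussian surrogate),
and the gate terms keep r_d open exactly where the posterior diverges
from the prior — dimensions with small KL are driven to r ≈ 0 and
flagged as nuisance.  Downstream, per-dimension Welch t-tests with
Benjamini–Hochberg correction (FDR q = 0.01) on a propensity-matched
cohort, counts of atypical occurrences (> 2 control SDs), and a
Pearson network thresholded at |r| > 0.2 characterize the latent
space; a [7, 4] head (or [512, 256, 128] with demographics) fine-tuned
jointly with the encoder does the classification.  See
`docs/methods.md` for the full account.

Everything — the VAE, its hand-written float64 backprop, the
discriminator, the classifier heads — runs on numpy; no deep-learning
framework is required.

## Worked example

```python
import numpy as np
from clockfactors import experiments as ex

# train the RF-VAE on 2,000 synthetic clocks varying 5 factors
rec = ex.factor_recovery_experiment(seed=1, n_clocks=2000)
print("factors recovered:", rec.n_recovered, "of 5")
print("nuisance dims flagged:", rec.n_nuisance)
print("matched |r|:", rec.matched_r.round(2))

# labeled cohort (84/263 fine-tune, 28/87 test) + group statistics
study = ex.build_cohort_study(seed=1)
gs = ex.group_statistics_experiment(study, features="factors")
print("size-factor |t| rank:", gs["size_t_rank"])

# classification with bootstrap CIs
cls = ex.classification_experiment(study, seed=1)
print("AUC latent-only:", round(cls["latent"].point["auc"], 3))
print("AUC + demographics:", round(cls["latent+demo"].point["auc"], 3))
```

prints (about 12 minutes on one CPU core):

```
factors recovered: 4 of 5
nuisance dims flagged: 4
matched |r|: [0.76 0.89 0.64 0.66 0.02]
size-factor |t| rank: 1
AUC latent-only: 0.938
AUC + demographics: 0.956
```

Reading: four of the five varied generative factors are tracked by a
distinct latent dimension (|Pearson r| between ground truth and latent
mean; the fifth, digit dropout, barely varies at its baseline and is
not recoverable), four unused dimensions were pruned by the relevance
gates, the size factor dominates the propensity-matched
dementia/control contrast exactly as the clinical pattern dictates,
and the fine-tuned classifier separates the confounded test cohort
with high AUC that improves when demographics are added (the synthetic
shifts are deliberately separable; clinical performance is a property
of clinical data).

There is also a CLI for file-based runs:

```bash
clockfactors run --out runs/demo --seed 1          # defaults throughout
clockfactors run --config my_run.yaml --out runs/x # or a YAML override
```

which writes the cohort (PNG + CSV), the trained model, traversal
montages, the group-comparison and network reports, and classifier
metrics under `runs/demo/`.

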
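"""Canonical desk-scale experiments for the clock-factor pipeline.

Each function runs one self-contained study on synthetic data —
factor recovery, TC-estimator calibration, group statistics,
classification, bootstrap coverage — and returns the measured
quantities.  The problem sizes are the package's desk-scale defaults
(see docs/methods.md §7); everything is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._nn import MLP
from .analysis import (compare_groups, correlation_network, count_atypical,
                       propensity_match)
from .classify import (HeadConfig, LabeledData, bootstrap_metrics,
                       bootstrap_ci, finetune)
from .preprocess import preprocess_page
from .rfvae import (RFVAE, TrainConfig, tc_estimate,
                    train, train_discriminator_to_convergence)
from .synthetic import CohortConfig, generate_cohort, subjects_frame

#: The five factors varied in the recovery experiment: the five with the
#: largest rendered-ink footprint, hence the ones a pixel-space
#: reconstruction objective can be expected to surface.
RECOVERY_FACTORS = ["size", "obovate", "prolate_oblate", "ellipse_tilt",
                    "digit_dropout"]

#: Desk-scale unsupervised training settings (methods note §3, §7).
DESK_TRAIN = dict(epochs=100, batch_size=64, learning_rate=1e-3,
                  tc_weight=6.4, relevance_sparsity=1.8,
                  kl_relevance_coupling=1.0, tc_estimator="gaussian")


def _stack_images(subjects, images):
    return np.stack([preprocess_page(images[s.id]).pixels for s in subjects])


def match_factors_to_latents(truth: np.ndarray, latents: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hungarian assignment of ground-truth factors to latent means by
    absolute Pearson correlation.  Returns (factor_idx, latent_idx, |r|)."""
    k, d = truth.shape[1], latents.shape[1]
    C = np.zeros((k, d))
    for i in range(k):
        for j in range(d):
            with np.errstate(invalid="ignore"):
                C[i, j] = np.corrcoef(truth[:, i], latents[:, j])[0, 1]
    C = np.nan_to_num(C)
    ri, cj = linear_sum_assignment(-np.abs(C))
    return ri, cj, np.abs(C[ri, cj])


@dataclass
class RecoveryResult:
    n_recovered: int
    n_nuisance: int
    matched_r: np.ndarray
    latent_of_factor: dict[str, int]
    kl_per_dim: np.ndarray
    relevance: np.ndarray
    model: RFVAE


def factor_recovery_experiment(seed: int, n_clocks: int = 2000,
                               epochs: int = DESK_TRAIN["epochs"],
                               r_threshold: float = 0.5) -> RecoveryResult:
    """Train the RF-VAE on clocks varying five independent factors and
    measure how many factors a distinct latent dimension recovers
    (|Pearson r| >= ``r_threshold`` under Hungarian matching), and how
    many of the remaining dimensions are flagged nuisance
    (relevance < 0.1 or mean prior KL < 0.05)."""
    cc = CohortConfig(n_train=n_clocks, n_finetune_dem=0, n_finetune_ctl=0,
                      n_test_dem=0, n_test_ctl=0, seed=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        subjects, images, truth = generate_cohort(cc, factors=RECOVERY_FACTORS)
    x = _stack_images(subjects, images)
    F = np.array([[getattr(truth[s.id], n) for n in RECOVERY_FACTORS]
                  for s in subjects])
    cfg = TrainConfig(seed=seed + 1, **{**DESK_TRAIN, "epochs": epochs})
    model, history = train(x, cfg, latent_dim=10)

    Z = model.latent_means(x)
    ri, cj, r_abs = match_factors_to_latents(F, Z)
    kl = history[[f"kl_{d}" for d in range(10)]].iloc[-1].to_numpy()
    rel = model.relevance.r
    rest = [d for d in range(10) if d not in set(cj)]
    n_nuis = sum(1 for d in rest if rel[d] < 0.1 or kl[d] < 0.05)
    return RecoveryResult(
        n_recovered=int((r_abs >= r_threshold).sum()),
        n_nuisance=int(n_nuis),
        matched_r=r_abs,
        latent_of_factor={RECOVERY_FACTORS[a]: int(b)
                          for a, b in zip(ri, cj)},
        kl_per_dim=kl, relevance=rel, model=model)


def tc_estimator_experiment(seed: int, n: int = 8192, rho: float = 0.9,
                            d: int = 10) -> dict[str, float]:
    """Calibrate the density-ratio TC estimator against the analytic
    Gaussian value: two coordinates correlated at ``rho`` (analytic TC
    = -0.5*ln(1-rho^2) ~ 0.830 at rho 0.9), the rest independent; and a
    fully factorized sample whose TC is zero."""
    rng = np.random.default_rng(seed)
    cov = np.eye(d)
    cov[0, 1] = cov[1, 0] = rho
    z_corr = rng.multivariate_normal(np.zeros(d), cov, size=n)
    z_fact = rng.standard_normal((n, d))
    out = {}
    for name, z in (("correlated", z_corr), ("factorized", z_fact)):
        disc = MLP([d, 64, 64, 1], np.random.default_rng(seed + 7))
        train_discriminator_to_convergence(
            disc, z, np.random.default_rng(seed + 11), steps=2000)
        out[name] = tc_estimate(z, disc)
    out["analytic"] = float(-0.5 * np.log(1 - rho ** 2))
    return out


@dataclass
class CohortStudy:
    """A default-shift labeled cohort plus the RF-VAE trained on its
    unlabeled split — the substrate for group stats + classification."""

    subjects: pd.DataFrame
    images64: np.ndarray
    truth: pd.DataFrame
    model: RFVAE | None

    def labeled_mask(self) -> np.ndarray:
        return (self.subjects["label"] != "unlabeled").to_numpy()

    def pack(self, split: str) -> LabeledData:
        part = self.subjects[self.subjects["split"] == split]
        idx = part.index.to_numpy()
        return LabeledData(
            images=self.images64[idx],
            labels=(part["label"] == "dementia").to_numpy(int),
            demographics=part[["age", "sex", "race",
                               "education"]].reset_index(drop=True),
            ids=part["id"].tolist())


def build_cohort_study(seed: int, n_train: int = 2000,
                       epochs: int = DESK_TRAIN["epochs"],
                       train_model: bool = True) -> CohortStudy:
    """Generate the default labeled cohort (84/263 fine-tune, 28/87
    test, default dementia shifts, confounded demographics) and train
    the RF-VAE on its unlabeled split (skipped when ``train_model`` is
    False; factor-level analyses need no model)."""
    cc = CohortConfig(n_train=n_train, seed=seed)
    subjects, images, truth = generate_cohort(cc)
    x = _stack_images(subjects, images)
    df = subjects_frame(subjects)
    tf = pd.DataFrame([{"id": sid, **{n: getattr(fv, n) for n in
                                      fv.__dataclass_fields__}}
                       for sid, fv in truth.items()])
    model = None
    if train_model:
        cfg = TrainConfig(seed=seed + 2, **{**DESK_TRAIN, "epochs": epochs})
        model, _ = train(x[(df["split"] == "train").to_numpy()], cfg,
                         latent_dim=10)
    return CohortStudy(subjects=df, images64=x, truth=tf, model=model)


def group_statistics_experiment(study: CohortStudy, ratio: int = 2,
                                features: str = "latent"
                                ) -> dict[str, object]:
    """Propensity-matched Welch/BH comparison and atypicality counts on
    the labeled clocks.

    ``features="latent"`` analyzes the RF-VAE posterior means and
    identifies the size-matched latent; ``features="factors"`` analyzes
    the per-clock generative factor table directly (each column is a
    perfectly disentangled latent), isolating the statistics pipeline
    from representation quality.  Returns the size column's rank by
    |Welch t| and by atypical count, plus the full comparison table.
    """
    from .synthetic import FACTOR_NAMES

    df = study.subjects
    labeled = df[df["label"] != "unlabeled"]
    idx = labeled.index.to_numpy()
    y = (labeled["label"] == "dementia").to_numpy()
    truth = study.truth.set_index("id").loc[labeled["id"]]

    if features == "factors":
        Z = truth[FACTOR_NAMES].to_numpy()
        size_dim = FACTOR_NAMES.index("size")
        corr_size = np.zeros(Z.shape[1])
        corr_size[size_dim] = 1.0
    elif features == "latent":
        Z = study.model.latent_means(study.images64[idx])
        # identify the size dimension on controls only: within a group
        # the generative factors are independent, whereas pooling both
        # groups correlates every shifted factor with the rest via the
        # label
        F = truth[["size"]].to_numpy()
        corr_size = np.array([abs(np.corrcoef(F[~y, 0], Z[~y, j])[0, 1])
                              for j in range(Z.shape[1])])
        size_dim = int(np.argmax(corr_size))
    else:
        raise ValueError(f"unknown features {features!r}")

    match = propensity_match(labeled, ratio=ratio)
    pos = {sid: i for i, sid in enumerate(labeled["id"])}
    midx = np.array([pos[s] for s in match.matched["id"]])
    my = (match.matched["label"] == "dementia").to_numpy()
    comp = compare_groups(Z[midx], my, q=0.01)
    t_abs = comp.table["t"].abs().to_numpy()

    mu_c = Z[~y].mean(axis=0)
    sd_c = Z[~y].std(axis=0, ddof=1)
    counts = count_atypical(Z[y], mu_c, sd_c, k=2)

    return {
        "size_dim": size_dim,
        "size_corr": float(corr_size[size_dim]),
        "t_abs": t_abs,
        "size_t_rank": int((t_abs > t_abs[size_dim]).sum()) + 1,
        "atypical_counts": counts,
        "size_atypical_rank": int((counts > counts[size_dim]).sum()) + 1,
        "comparison": comp,
        "n_matched_cases": int(my.sum()),
        "n_matched_controls": int((~my).sum()),
        "n_significant": int(comp.significant.sum()),
    }


def planted_network_experiment(seed: int, n: int = 2000
                               ) -> dict[str, object]:
    """Three positively-correlated latent blocks with negative
    cross-block coupling; the thresholded Pearson network must recover
    exactly three subnetworks."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u -= u.mean(axis=0)

    def noise():
        return 0.8 * rng.normal(size=n)

    Z = np.column_stack([
        u[:, 0] + noise(), u[:, 0] + noise(),
        u[:, 1] - 0.45 * u[:, 0] + noise(),
        u[:, 1] - 0.45 * u[:, 0] + noise(),
        u[:, 2] - 0.45 * u[:, 1] + noise(),
        u[:, 2] - 0.45 * u[:, 1] + noise(),
    ])
    net = correlation_network(Z, threshold=0.2)
    return {"n_subnetworks": len(net.subnetworks), "network": net}


def classification_experiment(study: CohortStudy, seed: int,
                              bootstrap_B: int = 100) -> dict[str, object]:
    """Fine-tune the three classifier modes on the 84/263 set and
    evaluate on the 28/87 test set with bootstrap intervals."""
    ft, te = study.pack("finetune"), study.pack("test")
    out = {}
    configs = {
        "latent": HeadConfig(seed=seed),
        "latent+demo": HeadConfig.with_demographics(seed=seed + 1),
        "demo": HeadConfig.with_demographics(seed=seed + 2),
    }
    for mode, hc in configs.items():
        clf, _ = finetune(None if mode == "demo" else study.model,
                          hc, ft, mode=mode)
        rep = bootstrap_ci(clf, te, B=bootstrap_B,
                           rng=np.random.default_rng(seed + 17))
        out[mode] = rep
    return out


def coverage_experiment(seed: int, replications: int = 200, n_test: int = 115,
                        prevalence: float = 28 / 115, auc_target: float = 0.85,
                        B: int = 100) -> dict[str, float]:
    """Interval coverage of the bootstrap AUC CI under a binormal score
    model with known generating AUC.

    Scores are the cheap stand-in: negatives ~ N(0,1), positives ~
    N(mu,1) with mu = sqrt(2)*Phi^-1(AUC); each replication draws a
    fresh test set, bootstraps it B times and checks whether the 95%
    interval contains the generating AUC."""
    from scipy.stats import norm
    rng = np.random.default_rng(seed)
    mu = np.sqrt(2.0) * norm.ppf(auc_target)
    hits = 0
    for _ in range(replications):
        y = (rng.random(n_test) < prevalence).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.normal(0, 1, n_test) + mu * y
        rep = bootstrap_metrics(y, s, B=B, rng=rng, threshold=0.0)
        _, lo, hi = rep.metrics["auc"]
        hits += int(lo <= auc_target <= hi)
    return {"coverage": hits / replications, "replications": replications}
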
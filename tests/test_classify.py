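"""Classifier fine-tuning, metrics, bootstrap and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from clockfactors.classify import (HeadConfig, LabeledData, MetricsReport,
                                   auc_score, bootstrap_ci, bootstrap_metrics,
                                   cross_validate, evaluate, finetune,
                                   metrics_from_scores)
from clockfactors.rfvae import RFVAE


def auc_bruteforce(y, s):
    """Exhaustive pairwise concordance with half-credit ties."""
    pos = [si for si, yi in zip(s, y) if yi == 1]
    neg = [si for si, yi in zip(s, y) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def demo_frame(n, rng):
    return pd.DataFrame({
        "age": rng.normal(72, 6, n),
        "sex": rng.choice(["F", "M"], n),
        "race": rng.choice(["white", "other"], n),
        "education": rng.normal(14, 2, n),
    })


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.2]) == 1.0

    def test_three_of_four_concordant(self):
        # positives 0.9 and 0.6 vs negatives 0.7 and 0.3: one discordant pair
        assert auc_score([1, 1, 0, 0], [0.9, 0.6, 0.7, 0.3]) == 0.75

    def test_matches_exhaustive_concordance(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(4, 50)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)       # induces ties
            assert auc_score(y, s) == pytest.approx(auc_bruteforce(y, s),
                                                    abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        base = auc_score(y, s)
        for f in (np.exp, np.tanh, lambda v: 3 * v - 7):
            assert auc_score(y, f(s)) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([1, 1], [0.2, 0.4])


class TestConfusionMetrics:
    def test_confusion_arithmetic(self):
        # TP=2, FN=1, FP=1, TN=6
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        m = metrics_from_scores(y, s)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(6 / 7)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["npv"] == pytest.approx(6 / 7)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_all_metrics_in_unit_interval(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        m = metrics_from_scores(y, rng.random(30))
        for name in ("auc", "accuracy", "f1", "precision", "sensitivity",
                     "specificity", "npv"):
            assert 0.0 <= m[name] <= 1.0

    def test_f1_zero_when_no_positive_predictions(self):
        m = metrics_from_scores([1, 0, 1], [0.1, 0.2, 0.3])
        assert m["precision"] == 0.0 and m["sensitivity"] == 0.0
        assert m["f1"] == 0.0


class TestBootstrap:
    def test_perfect_predictions_degenerate_intervals(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        s = y.astype(float)
        rep = bootstrap_metrics(y, s, B=50, rng=np.random.default_rng(0))
        for name, (med, lo, hi) in rep.metrics.items():
            assert (med, lo, hi) == (1.0, 1.0, 1.0), name

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        s = np.clip(y + rng.normal(0, 0.6, 60), 0, 1)
        r1 = bootstrap_metrics(y, s, B=100, rng=np.random.default_rng(42))
        r2 = bootstrap_metrics(y, s, B=100, rng=np.random.default_rng(42))
        assert r1.metrics == r2.metrics

    def test_interval_ordering_invariant(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        rep = bootstrap_metrics(y, s, B=100, rng=rng)
        for med, lo, hi in rep.metrics.values():
            assert lo <= med <= hi

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="lo <= median <= hi"):
            MetricsReport(metrics={"auc": (0.5, 0.6, 0.9)}, n_resamples=10)

    def test_too_few_resamples(self):
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_metrics(np.array([1, 0]), np.array([0.9, 0.1]), B=1)


def pretrained_encoder(seed=0):
    """An encoder with a non-degenerate posterior map (stands in for the
    unsupervised pretraining stage, which moves the zero-initialized
    posterior head away from the prior)."""
    m = RFVAE(latent_dim=10, seed=seed)
    rng = np.random.default_rng(seed + 100)
    head = m.encoder.layers[-1].W
    head.value += rng.normal(0, 0.01, head.value.shape)
    return m


def separable_data(n=80, rng=None, with_demo=False):
    """Images whose ink mass separates the classes (proxy for size)."""
    rng = rng or np.random.default_rng(0)
    y = (np.arange(n) % 2 == 0).astype(int)
    imgs = np.ones((n, 64, 64))
    for i in range(n):
        r = 8 + 6 * y[i] + rng.integers(0, 3)
        imgs[i, 32 - r:32 + r, 32 - r:32 + r] = 0.2
    return LabeledData(images=imgs, labels=y,
                       demographics=demo_frame(n, rng) if with_demo else None)


class TestFinetune:
    def test_separable_data_learned(self):
        data = separable_data(n=60)
        model = pretrained_encoder()
        cfg = HeadConfig(seed=1)
        clf, history = finetune(model, cfg, data)
        assert history["loss"].iloc[-1] < history["loss"].iloc[0]
        assert auc_score(data.labels, clf.predict_proba(data)) > 0.95

    def test_seeded_determinism(self):
        data = separable_data(n=40)
        model = RFVAE(latent_dim=10, seed=0)
        clf1, _ = finetune(model, HeadConfig(seed=5), data)
        clf2, _ = finetune(model, HeadConfig(seed=5), data)
        assert np.array_equal(clf1.head.layers[0].W.value,
                              clf2.head.layers[0].W.value)
        assert np.allclose(clf1.predict_proba(data), clf2.predict_proba(data))

    def test_finetuning_does_not_mutate_pretrained_encoder(self):
        data = separable_data(n=40)
        model = RFVAE(latent_dim=10, seed=0)
        before = model.encoder.layers[0].W.value.copy()
        finetune(model, HeadConfig(seed=1), data)
        assert np.array_equal(model.encoder.layers[0].W.value, before)

    def test_class_weight_boosts_sensitivity(self):
        """Upweighting the rare positive class cannot reduce sensitivity
        on an imbalanced fixture."""
        rng = np.random.default_rng(2)
        n = 120
        y = (np.arange(n) < 24).astype(int)     # 1:4 imbalance
        imgs = np.ones((n, 64, 64))
        for i in range(n):
            r = 8 + 4 * y[i] + rng.integers(0, 4)
            imgs[i, 32 - r:32 + r, 32 - r:32 + r] = 0.2
        data = LabeledData(images=imgs, labels=y)
        model = pretrained_encoder()
        sens = {}
        for w in (1.0, 3.125):
            clf, _ = finetune(model,
                              HeadConfig(seed=3, positive_class_weight=w),
                              data)
            sens[w] = evaluate(clf, data)["sensitivity"]
        assert sens[3.125] >= sens[1.0]

    def test_single_class_data_rejected(self):
        data = separable_data(n=20)
        data.labels[:] = 1
        with pytest.raises(ValueError, match="both classes"):
            finetune(RFVAE(latent_dim=10, seed=0), HeadConfig(), data)

    def test_demographics_modes(self):
        data = separable_data(n=40, with_demo=True)
        model = RFVAE(latent_dim=10, seed=0)
        for mode, dim in (("latent", 10), ("latent+demo", 14), ("demo", 4)):
            clf, _ = finetune(None if mode == "demo" else model,
                              HeadConfig(seed=1), data, mode=mode)
            assert clf.input_dim == dim
            assert clf.predict_proba(data).shape == (40,)

    def test_bootstrap_ci_end_to_end(self):
        data = separable_data(n=60)
        model = pretrained_encoder()
        clf, _ = finetune(model, HeadConfig(seed=1), data)
        rep = bootstrap_ci(clf, data, B=50, rng=np.random.default_rng(0))
        assert rep.n_resamples == 50
        lo, med, hi = (rep.metrics["auc"][1], rep.metrics["auc"][0],
                       rep.metrics["auc"][2])
        assert 0 <= lo <= med <= hi <= 1


class TestCrossValidate:
    def test_single_configuration_returned(self):
        data = separable_data(n=50)
        model = pretrained_encoder()
        cfg = HeadConfig(seed=1)
        best, table = cross_validate([cfg], model, data, folds=5)
        assert best is cfg
        assert len(table) == 5

    def test_cv_table_bookkeeping(self):
        data = separable_data(n=50)
        model = pretrained_encoder()
        space = [HeadConfig(hidden_sizes=(7, 4), seed=1),
                 HeadConfig(hidden_sizes=(2,), seed=1)]
        best, table = cross_validate(space, model, data, folds=5)
        assert len(table) == 10
        assert set(table["fold"]) == set(range(5))

    def test_majority_class_config_never_wins(self):
        """A head too crippled to learn loses to a separating
        configuration; a constant predictor scores AUC 1/2."""
        data = separable_data(n=50)
        model = pretrained_encoder()
        crippled = HeadConfig(hidden_sizes=(1,), learning_rate=1e-12, seed=1)
        good = HeadConfig(seed=1)
        best, table = cross_validate([crippled, good], model, data, folds=5)
        assert best is good
        assert (table[table["config"] == 1]["auc"].mean()
                > table[table["config"] == 0]["auc"].mean())
        # a majority-class (constant-score) predictor sits at AUC 1/2
        assert auc_score(data.labels, np.full(50, 0.5)) == 0.5

    def test_empty_search_space(self):
        with pytest.raises(ValueError, match="empty"):
            cross_validate([], None, separable_data(n=20), folds=2)
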
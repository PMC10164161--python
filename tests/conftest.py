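"""Shared fixtures: small rendered clocks and a tiny trained RF-VAE."""

import numpy as np
import pytest

from clockfactors.preprocess import preprocess_page
from clockfactors.rfvae import RFVAE, TrainConfig, train
from clockfactors.synthetic import (CohortConfig, FactorVector,
                                    generate_cohort, render_clock)


@pytest.fixture(scope="session")
def ideal_clock_page() -> np.ndarray:
    return render_clock(FactorVector(), 256, 3, np.random.default_rng(0))


@pytest.fixture(scope="session")
def ideal_clock_64(ideal_clock_page):
    return preprocess_page(ideal_clock_page)


@pytest.fixture(scope="session")
def small_cohort():
    """A small labeled cohort with the default dementia shifts."""
    cc = CohortConfig(n_train=80, n_finetune_dem=20, n_finetune_ctl=40,
                      n_test_dem=10, n_test_ctl=20, seed=7)
    subjects, images, truth = generate_cohort(cc)
    x = np.stack([preprocess_page(images[s.id]).pixels for s in subjects])
    return cc, subjects, x, truth


@pytest.fixture(scope="session")
def tiny_trained_vae(small_cohort):
    """An RF-VAE briefly trained on the small cohort's train split."""
    _, subjects, x, _ = small_cohort
    mask = np.array([s.split == "train" for s in subjects])
    cfg = TrainConfig(epochs=8, batch_size=40, learning_rate=1e-3, seed=3)
    model, history = train(x[mask], cfg, latent_dim=10)
    return model, history
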
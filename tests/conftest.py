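"""Shared fixtures: expensive trained networks are session-scoped."""

import numpy as np
import pytest

from v1sal.fixtures import (
    make_pink_noise_images,
    make_popout_scene,
    make_sparse_patch_set,
)
from v1sal.saliency import compute_saliency
from v1sal.sparse_net import SparseCodingModel, TrainingConfig, sample_patches


@pytest.fixture(scope="session")
def trained_rf():
    """Receptive fields trained on pink-noise surrogate images (seed 0)."""
    images = make_pink_noise_images(n=20, size=128, seed=0)
    patches = sample_patches(images, 20_000, 14, seed=0)
    cfg = TrainingConfig(seed=0, n_epochs=15)
    return SparseCodingModel(patches, cfg).fit().receptive_fields


@pytest.fixture(scope="session")
def dict_fit():
    """Fit on sparse-dictionary patches; returns (results, true dictionary)."""
    patches, dictionary = make_sparse_patch_set(seed=5)
    cfg = TrainingConfig(patch_side=10, seed=5)
    results = SparseCodingModel(patches, cfg).fit()
    return results, dictionary


@pytest.fixture(scope="session")
def popout_battery(trained_rf):
    """Saliency results for 20 seeded pop-out scenes: list of (mask, result)."""
    out = []
    for seed in range(20):
        img, mask = make_popout_scene(seed=seed)
        res = compute_saliency(img, trained_rf, stride=2)
        out.append((mask, res))
    return out
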
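"""Shared fixtures: seeded rngs and one session-scoped trained tiny detector."""

import numpy as np
import pytest

from gcdetect.detector import tiny_config, train
from gcdetect.synthetic_scenes import SceneConfig, class_name, generate_annotated


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMOKE_CLASSES = 5
SMOKE_NAMES = [class_name(k) for k in range(SMOKE_CLASSES)]


def smoke_scene_config(seed: int = 7, n_extra=None) -> SceneConfig:
    """Small, quick-to-render scenes shared by training smoke tests."""
    return SceneConfig(num_classes=SMOKE_CLASSES, image_size=(96, 96),
                       s_min=10, s_max=28, max_targets=3, seed=seed)


@pytest.fixture(scope="session")
def smoke_dataset():
    """60 small scenes: 48 train + 12 held out."""
    anns = generate_annotated(60, smoke_scene_config())
    return anns[:48], anns[48:]


@pytest.fixture(scope="session")
def trained_tiny(smoke_dataset):
    """One tiny attention-enabled detector trained briefly on synthetic scenes.

    Shared across tests that need a model which has actually learned
    something (prediction smoke, activation heatmaps); kept deliberately
    short so the suite stays fast.
    """
    train_set, _ = smoke_dataset
    cfg = tiny_config(SMOKE_CLASSES, gct_placement="layer123",
                      cbam_locations=("C2", "C3"), regression_loss="eiou")
    cfg.batch_size = 2
    model, history = train(train_set, cfg, None, seed=5,
                           class_names=SMOKE_NAMES, epochs=6)
    return model, history
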
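"""Shared fixtures: desk-scale phantoms and a model overfit to one of them.

The overfit model is expensive (a few minutes of CPU training) and is
shared, session-scoped, by the training, sensitivity, and saliency tests.
"""

import numpy as np
import pytest

from mhseg.experiments import DESK_PATCH, DESK_SPEC, desk_infer_config
from mhseg.models import ModelConfig, build_model
from mhseg.phantom import generate_study
from mhseg.preprocess import prepare_study
from mhseg.training import TrainConfig, train


@pytest.fixture(scope="session")
def desk_study():
    """One noiseless, undistorted, normalized phantom study."""
    return prepare_study(generate_study(DESK_SPEC.model_copy(update={"seed": 11})))


@pytest.fixture(scope="session")
def noisy_distorted_study():
    spec = DESK_SPEC.model_copy(update={"seed": 21, "noise_sigma": 0.05,
                                        "distortion_magnitude_mm": 3.0})
    return prepare_study(generate_study(spec))


@pytest.fixture(scope="session")
def overfit_model(desk_study):
    """Width-0.25 multihead_3 trained 500 seeded iterations on one
    noiseless, undistorted phantom (train == val == that phantom)."""
    model = build_model(ModelConfig(variant="multihead_3", width_multiplier=0.25),
                        seed=7)
    cfg = TrainConfig(iterations=500, epoch_length=100, batch_size=1,
                      patch_size=DESK_PATCH, seed=7, augment_probability=0.0)
    result = train(model, [desk_study], [desk_study], cfg,
                   infer_cfg=desk_infer_config())
    model.load_state_dict(result.best_state)
    return model, result


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
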
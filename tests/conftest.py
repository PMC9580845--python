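"""Shared fixtures, including the session-scoped trained smoke model.

The smoke model is a deliberately small network (8 base filters) trained
for 10 epochs on 20 small synthetic stacks; several end-to-end tests share
it so the training cost is paid once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lungmet.loss import LossConfig
from lungmet.network import NetworkSpec, build_network
from lungmet.phantom import PhantomSpec, generate_phantom
from lungmet.train import TrainConfig, split_dataset, train_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

#: Study conditions of the end-to-end learning smoke test.
SMOKE_DIMS = (32, 64, 64)
SMOKE_N_STACKS = 20
SMOKE_TINY_SPEC = NetworkSpec(base_filters=8, skip_channels_per_scale=8)
SMOKE_TRAIN = TrainConfig(epochs=10, batch_size=16, seed=0, lr_max=0.003)
SMOKE_RADIUS_RANGE = (2.8, 4.2)
SMOKE_HELDOUT_SEED = 999


def smoke_training_slices():
    pairs = []
    for i in range(SMOKE_N_STACKS):
        spec = PhantomSpec.random(
            dims=SMOKE_DIMS, n_metastases=3, seed=100 + i,
            radius_range=SMOKE_RADIUS_RANGE,
        )
        stack, labels = generate_phantom(spec)
        img = stack.normalized()
        for z in range(SMOKE_DIMS[0]):
            if (labels.data[z] > 0).any():
                pairs.append((img[z], labels.data[z]))
    return pairs


def smoke_heldout_phantom():
    spec = PhantomSpec.random(
        dims=SMOKE_DIMS, n_metastases=3, seed=SMOKE_HELDOUT_SEED,
        radius_range=(3.0, 4.0),
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def trained_smoke_model():
    """Tiny network trained on synthetic stacks; shared across the session."""
    pairs = smoke_training_slices()
    train_set, val_set = split_dataset(pairs, SMOKE_TRAIN.split_ratio, SMOKE_TRAIN.seed)
    model = build_network(SMOKE_TINY_SPEC, seed=SMOKE_TRAIN.seed)
    train_model(model, train_set, val_set, LossConfig(), SMOKE_TRAIN)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
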
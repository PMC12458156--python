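"""Shared fixtures: simulation conditions and a trained toy model.

The few-shot training fixture is session-scoped because training, while
fast, is the most expensive step; several test modules share one trained
model (training determinism is verified separately on a short run).
"""

import dataclasses

import numpy as np
import pytest

import fewpick as fp

# high-SNR few-shot study conditions for the end-to-end checks
E2E_SIZE = 64
E2E_DIAMETER = 12.0
E2E_SIM = fp.SimParams(
    image_size=E2E_SIZE,
    n_particles=6,
    particle_diameter=E2E_DIAMETER,
    snr=8.0,
    overlap_fraction=0.0,
    n_ice_blobs=0,
    contrast_jitter=0.2,
    seed=11,
)
E2E_CONFIG = fp.TrainConfig(
    max_epochs=400, learning_rate=5e-3, input_size=E2E_SIZE, seed=0
)


@pytest.fixture(scope="session")
def trained_toy():
    """Toy model trained on 5 high-SNR synthetic shots, plus held-out data.

    Returns a dict with the model, the loss trace, the held-out
    (micrograph, ground truth) pairs, and a bitwise copy of the backbone
    taken before training.
    """
    train_set = fp.make_fewshot_dataset(5, E2E_SIM)
    held = fp.make_fewshot_dataset(
        5, dataclasses.replace(E2E_SIM, seed=E2E_SIM.seed + 1000)
    )
    model = fp.build_toy_model(input_size=E2E_SIZE, seed=0)
    backbone_before = model.backbone.state_copy()
    pairs = [(m, g.mask) for m, g in train_set]
    trace = fp.train_few_shot(pairs, model, E2E_CONFIG)
    return {
        "model": model,
        "trace": trace,
        "train_pairs": pairs,
        "held": held,
        "backbone_before": backbone_before,
    }


@pytest.fixture(scope="session")
def toy_specs():
    return fp.make_stage_specs("toy", toy_scale=8)
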
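"""Bundled experiment configurations.

``full_scale_*`` mirrors the published protocol (300 epochs, learning rate
1e-4, batch size 1, dropout 0.8, 32-channel base width) and is what a GPU
user would run. ``desk_*`` is the CPU-scale variant every test and example
uses: 64 x 64 synthetic ROIs, a 4-channel-base U-net, 30 epochs per
iteration, a larger learning rate so Adam converges in the shorter schedule,
and milder dropout (0.8 of a 4-channel feature map leaves no signal).
"""

from __future__ import annotations

from .synthetic import CohortConfig, desk_preset, paper_like_preset
from .unet import ModelSpec, TrainConfig

__all__ = [
    "full_scale_model_spec",
    "full_scale_train_config",
    "desk_model_spec",
    "desk_train_config",
    "desk_preset",
    "paper_like_preset",
]

N_HOLDOUT_PATIENTS = 3
N_BOOTSTRAP = 4
N_ITERATIONS = 3
N_RL_BATCHES = 3


def full_scale_model_spec(n_classes: int = 11) -> ModelSpec:
    return ModelSpec(n_classes=n_classes, depth=4, base_channels=32, dropout_rate=0.8)


def full_scale_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=300, learning_rate=1e-4, batch_size=1, seed=seed)


def desk_model_spec(n_classes: int = 11) -> ModelSpec:
    return ModelSpec(n_classes=n_classes, depth=4, base_channels=8, dropout_rate=0.25)


def desk_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    return TrainConfig(epochs=epochs, learning_rate=3e-3, batch_size=1, seed=seed)
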
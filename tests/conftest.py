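"""Shared fixtures: legends, lightweight cohorts, and the desk-scale
AL-vs-RL experiment (session-scoped; several tests read different aspects of
the same runs)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import alseg
from alseg.legend import LabelMap, RoiSample, split_by_patient, table1_legend
from alseg.presets import desk_model_spec, desk_preset, desk_train_config

EXPERIMENT_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def legend():
    return table1_legend()


def make_sample(roi_id, patient_id, labels, legend, mpp=2.0, rng=None):
    """RoiSample with a deterministic filler image matching the label shape."""
    labels = np.asarray(labels, dtype=np.int16)
    rng = rng or np.random.default_rng(0)
    image = rng.integers(0, 256, size=labels.shape + (3,), dtype=np.uint8)
    return RoiSample(
        roi_id=roi_id,
        patient_id=patient_id,
        image=image,
        labels=LabelMap(labels, legend),
        microns_per_pixel=mpp,
    )


@pytest.fixture()
def tiny_cohort(legend):
    """24 ROIs over 23 patients (patient P00 contributes two), 4x4 label maps."""
    rng = np.random.default_rng(7)
    samples = []
    for p in range(23):
        n = 2 if p == 0 else 1
        for r in range(n):
            labels = rng.integers(0, legend.n_classes, size=(4, 4))
            samples.append(make_sample(f"P{p:02d}R{r}", f"P{p:02d}", labels, legend, rng=rng))
    return samples


@pytest.fixture(scope="session")
def desk_experiment():
    """The scaled-down AL-vs-RL study: one full experiment per seed.

    Each experiment = shared bootstrap C0, 3 AL iterations, 3 RL batches of 3
    iterations, holdout evaluation of every classifier version.
    """
    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in EXPERIMENT_SEEDS:
            cohort, _ = alseg.generate_cohort(desk_preset(seed=seed))
            split = split_by_patient(cohort, 3, seed=seed)
            results[seed] = alseg.run_experiment(
                cohort,
                split,
                desk_model_spec(),
                desk_train_config(),
                n_iterations=3,
                n_rl_batches=3,
                seed=seed,
            )
    return results
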
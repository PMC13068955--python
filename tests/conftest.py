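"""Shared fixtures.

The expensive fixture is ``trained_dcs``: one (or, if the stochastic Dice
check fails, up to three) test-profile training runs of the joint
classification+segmentation model on synthetic phantom exams.  It is
session-scoped so the segmentation acceptance experiment, the invariance
tests and the pipeline integration tests all share the same trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from fontanflow import dcs, phantom as ph
from fontanflow.flowquant import dice

DCS_SEEDS = (101, 102, 103)
DICE_THRESHOLD = 0.85
N_TRAIN_EXAMS = 20
N_TEST_EXAMS = 5


def make_exams(n, seed, grid=32, frames=8, jitter=0.03):
    rng = np.random.default_rng(seed)
    return [ph.generate_phantom_exam(
                ph.default_phantom_spec(grid_size=(grid, grid), n_frames=frames,
                                        jitter=jitter, rng=rng),
                exam_id=f"e{seed}_{i}", patient_id=f"p{seed}_{i}", rng=rng)
            for i in range(n)]


def _train_once(seed):
    cfg = dcs.DCSConfig.test_profile(seed=seed)
    exams = make_exams(N_TRAIN_EXAMS + N_TEST_EXAMS, seed=seed)
    train, test = exams[:N_TRAIN_EXAMS], exams[N_TRAIN_EXAMS:]
    model, history = dcs.train_dcs(train, cfg)
    test_samples = dcs.prepare_training_samples(test, cfg)
    dices, correct = [], 0
    for s in test_samples:
        cls, mask, _ = model.predict(s)
        dices.append(dice(mask, s.truth_mask))
        correct += cls == dcs.CLASSES[s.truth_class]
    return {"seed": seed, "model": model, "history": history,
            "test_exams": test, "test_samples": test_samples,
            "median_dice": float(np.median(dices)),
            "dices": dices, "classification_acc": correct / len(test_samples)}


@pytest.fixture(scope="session")
def trained_dcs():
    """Train the test-profile model on 20 phantom exams (60 epochs).

    The headline Dice check is stochastic, so up to three seeds are tried;
    training stops as soon as two runs clear the threshold (or a second
    failure makes that impossible).
    """
    runs = []
    passes = fails = 0
    for seed in DCS_SEEDS:
        run = _train_once(seed)
        runs.append(run)
        if run["median_dice"] >= DICE_THRESHOLD:
            passes += 1
        else:
            fails += 1
        if passes == 2 or fails == 2:
            break
    best = max(runs, key=lambda r: r["median_dice"])
    return {"runs": runs, "passes": passes, "best": best,
            "model": best["model"]}


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 4-archetype flow cohort, one scan per patient."""
    spec = ph.CohortSpec(archetypes=ph.VC_ARCHETYPES, n_per_cluster=50,
                         seed=7, scan_probs=(1.0,))
    curves, labels, demo = ph.generate_flow_cohort(spec)
    return spec, curves, labels, demo


@pytest.fixture()
def phantom_exam():
    return make_exams(1, seed=42)[0]
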
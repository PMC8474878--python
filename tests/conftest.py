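"""Shared fixtures: synthetic datasets and a trained model, built once."""

from __future__ import annotations

import numpy as np
import pytest

from szcast import evaluate as ev
from szcast import network as nn
from szcast import preprocess as pp
from szcast import synth as sy

SEIZURE_ONSETS_MIN = (50, 170, 290)


def _make_config(effect: float, seed: int = 7) -> sy.SynthConfig:
    return sy.SynthConfig(
        n_channels=2,
        duration_s=6 * 3600,
        preictal_effect=effect,
        preictal_len_min=35.0,
        seed=seed,
        start_clock_s=12 * 3600,
        affected_channels=[0, 1],
    )


def make_labeled_segments(effect: float, seed: int = 7):
    """Generate a 6-h, 2-channel recording with three seizures and return
    (segments, schedule, config)."""
    cfg = _make_config(effect, seed)
    schedule = [
        pp.SeizureAnnotation(m * 60.0, (m + 1) * 60.0) for m in SEIZURE_ONSETS_MIN
    ]
    rec = sy.generate_recording(cfg, schedule)
    segments = pp.segments_from_recording(
        rec,
        schedule,
        interictal_margin_h=0.5,
        max_windows_per_class=400,
        seed=seed,
    )
    return segments, schedule, cfg


#: Desk-scale training settings: the reference defaults (lr 1e-3, sigma 0.05)
#: need more epochs than the test budget allows, so tests run a faster,
#: lower-noise configuration that is stable across seeds.
def desk_train_config(**overrides) -> "nn.TrainConfig":
    kwargs = dict(epochs=15, learning_rate=5e-3, sigma_init=0.01, seed=0)
    kwargs.update(overrides)
    return nn.TrainConfig(**kwargs)


def split_segments(segments, seed: int = 0, train_frac: float = 0.7):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(segments))
    n_train = int(train_frac * len(segments))
    return (
        [segments[i] for i in idx[:n_train]],
        [segments[i] for i in idx[n_train:]],
    )


def mean_score_auc(spec, layers, test_segments, S: int = 50, seed: int = 1,
                   fusion_factors=None) -> float:
    preds = nn.mc_predict_batch(
        spec, layers, test_segments, S=S, seed=seed, fusion_factors=fusion_factors
    )
    scores = [p.scores.mean() for p in preds]
    labels = [1 if s.label == "preictal" else 0 for s in test_segments]
    return ev.segment_auc(scores, labels)


@pytest.fixture(scope="session")
def separable_data():
    """Strong-signature dataset (preictal_effect = 4) with a held-out split."""
    segments, schedule, cfg = make_labeled_segments(effect=4.0)
    train_set, test_set = split_segments(segments)
    return {
        "segments": segments,
        "schedule": schedule,
        "config": cfg,
        "train": train_set,
        "test": test_set,
    }


@pytest.fixture(scope="session")
def trained_model(separable_data):
    """Reduced-width variational network trained on the separable dataset."""
    spec = nn.default_spec(2, width_scale=0.25)
    layers, trace = nn.train(spec, separable_data["train"], desk_train_config())
    return {"spec": spec, "layers": layers, "trace": trace}
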
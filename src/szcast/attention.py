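"""Biomarker probe: time-resolved attention from first-layer feature maps.

High-confidence preictal segments (uncertainty level below 0.1, mean score
above 0.9 by default) are selected, and for each one an attention profile is
computed by rectifying the first convolutional layer's feature map and
summing over the kernel and frequency axes, leaving one value per
first-layer time index.  Averaging the profile over many posterior weight
realizations smooths sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import NetworkSpec, VariationalLayer, forward, sample_weights
from .preprocess import STFTSegment
from .uncertainty import UncertaintyEstimate


@dataclass
class AttentionProfile:
    """Non-negative attention over the first conv layer's time axis."""

    values: np.ndarray
    segment_ref: int = -1
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("attention values must be non-negative")

    def normalized(self) -> "AttentionProfile":
        peak = self.values.max() if self.values.size else 0.0
        vals = self.values / peak if peak > 0 else self.values.copy()
        return AttentionProfile(vals, self.segment_ref, "max1")


def select_confident_segments(
    predictions: Sequence[UncertaintyEstimate],
    level_max: float = 0.1,
    mean_min: float = 0.9,
) -> list[int]:
    """Indices with uncertainty level strictly below ``level_max`` and mean
    score strictly above ``mean_min``."""
    return [
        i
        for i, e in enumerate(predictions)
        if e.level < level_max and e.mean_score > mean_min
    ]


def accumulate_attention(feature_map: np.ndarray) -> np.ndarray:
    """Rectify-and-sum one feature map (kernels, time, freq) -> per-time values."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3:
        raise ValueError(
            f"feature map must have rank 3 (kernels, time, freq), got rank {fm.ndim}"
        )
    return np.maximum(fm, 0.0).sum(axis=(0, 2))


def attention_map(
    spec: NetworkSpec,
    layers: Sequence[VariationalLayer],
    segment: STFTSegment | np.ndarray,
    samples: int = 100,
    seed: int = 0,
    normalize: bool = False,
    segment_ref: int = -1,
) -> AttentionProfile:
    """Posterior-averaged attention profile for one segment.

    Runs ``samples`` weight realizations, accumulates the rectified
    first-layer feature map over kernel and frequency axes at each time
    index, and averages across realizations.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(samples):
        real = sample_weights(spec, layers, rng)
        _, fm = forward(spec, real, segment)
        if fm is None:
            raise ValueError("spec has no convolutional layer to probe")
        prof = accumulate_attention(fm)
        acc = prof if acc is None else acc + prof
    profile = AttentionProfile(acc / samples, segment_ref)
    return profile.normalized() if normalize else profile


def time_axis_seconds(
    spec: NetworkSpec, window_s: float = 30.0, n_frames: int = 56
) -> np.ndarray:
    """Map first-layer time indices back to seconds inside the input window."""
    from .network import ConvSpec

    conv = next(l for l in spec.layers if isinstance(l, ConvSpec))
    stride_t, kernel_t = conv.stride[0], conv.kernel[0]
    out_len = (spec.input_shape[0] - kernel_t) // stride_t + 1
    sec_per_frame = window_s / (n_frames + 3)  # hop of the original STFT grid
    centers = (np.arange(out_len) * stride_t + (kernel_t - 1) / 2 + 1) * sec_per_frame
    return centers
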
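"""Decision-uncertainty quantification from Monte-Carlo prediction samples.

The uncertainty level is the sample standard deviation of the Monte-Carlo
scores divided by the distance of their mean from 0.5, so a uniform-like
score distribution (mean near 0.5) is maximally uncertain.  For display the
level is capped at 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import PredictionSamples

DISPLAY_CAP = 10.0
#: Default confidence gate used by the biomarker probe.
DEFAULT_CONFIDENT_LEVEL = 0.1

PredictionClass = Literal["confident_correct", "confident_wrong", "confident", "uncertain"]


@dataclass(frozen=True)
class UncertaintyEstimate:
    mean_score: float
    std_score: float
    level: float
    display_level: float


def uncertainty_level(samples: PredictionSamples) -> UncertaintyEstimate:
    """std(samples) / |mean(samples) - 0.5| with sample (n-1) std.

    A zero denominator yields +infinity internally and the display cap (10)
    for presentation.
    """
    scores = samples.scores
    mean = float(scores.mean())
    std = float(scores.std(ddof=1))
    denom = abs(mean - 0.5)
    level = std / denom if denom > 0 else float("inf")
    return UncertaintyEstimate(mean, std, level, min(level, DISPLAY_CAP))


def classify_prediction(
    estimate: UncertaintyEstimate,
    truth: int | None = None,
    confident_threshold: float = DEFAULT_CONFIDENT_LEVEL,
) -> PredictionClass:
    """Taxonomy of predictions: confident (correct/wrong) vs uncertain."""
    if estimate.level > confident_threshold:
        return "uncertain"
    if truth is None:
        return "confident"
    predicted = int(round(estimate.mean_score))
    return "confident_correct" if predicted == truth else "confident_wrong"
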
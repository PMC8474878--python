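"""Forecasting evaluation: AUC, seizure-period folds, gated risk timelines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .preprocess import STFTSegment, SeizureAnnotation


@dataclass(frozen=True)
class AlarmConfig:
    """Alarm timing: no onset within sph_min after an alarm; onset expected
    within the following sop_min.  The forecast window is
    [sph_min, sph_min + sop_min] minutes before onset."""

    sph_min: float = 5.0
    sop_min: float = 30.0

    def __post_init__(self) -> None:
        if self.sph_min < 0:
            raise ValueError("sph_min must be >= 0")
        if self.sop_min <= 0:
            raise ValueError("sop_min must be > 0")

    @property
    def window_min(self) -> tuple[float, float]:
        return (self.sph_min, self.sph_min + self.sop_min)


def segment_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve over segment scores; ties contribute 1/2."""
    labels = np.asarray(list(labels), dtype=int)
    scores = np.asarray(list(scores), dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class RiskTimeline:
    """Uncertainty-gated, backward-smoothed risk scores; gated-out points
    carry NaN in ``smoothed_scores`` rather than zero."""

    times_s: np.ndarray
    raw_scores: np.ndarray
    uncertainties: np.ndarray
    smoothed_scores: np.ndarray


def risk_timeline(
    predictions: Sequence[tuple[float, float, float]],
    smooth_window: int = 50,
    uncertainty_gate: float = 1.0,
) -> RiskTimeline:
    """Gate and smooth a time-ordered (time_s, mean_score, uncertainty) series.

    Points with uncertainty above the gate are discarded (NaN in the
    smoothed series); retained points get a backward moving average over the
    most recent ``min(smooth_window, available)`` retained points.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    if not predictions:
        return RiskTimeline(np.array([]), np.array([]), np.array([]), np.array([]))
    arr = np.asarray(predictions, dtype=float)
    times, scores, uncs = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(np.diff(times) <= 0):
        raise ValueError("prediction times must be strictly increasing")
    smoothed = np.full(len(times), np.nan)
    kept: list[float] = []
    for i, (s, u) in enumerate(zip(scores, uncs)):
        if u > uncertainty_gate:
            continue
        kept.append(s)
        smoothed[i] = float(np.mean(kept[-smooth_window:]))
    return RiskTimeline(times, scores, uncs, smoothed)


@dataclass
class PeriodFold:
    """One seizure-period cross-validation fold (index lists into segments)."""

    period: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def period_split(
    segments: Sequence[STFTSegment],
    leading: Sequence[SeizureAnnotation],
) -> list[PeriodFold]:
    """One fold per inter-ictal-bounded period.

    Period k spans from the previous leading seizure's onset (or the
    recording start) up to leading onset k.  Its fold tests on every segment
    inside the period and trains on all segments from other periods, so the
    model evaluated on a period never saw that period's preictal data.
    """
    if len(leading) < 2:
        raise ValueError(
            "period split needs at least 2 leading seizures; a single period "
            "would leave no disjoint training data"
        )
    onsets = [s.onset_s for s in sorted(leading, key=lambda a: a.onset_s)]
    bounds = [-np.inf] + onsets[:-1] + [np.inf]
    starts = np.array([s.start_s for s in segments])
    period_of = np.searchsorted(np.array(onsets[:-1]), starts, side="right")
    folds = []
    for k in range(len(onsets)):
        test_idx = np.flatnonzero(period_of == k)
        train_idx = np.flatnonzero(period_of != k)
        if len(test_idx) and len(train_idx):
            folds.append(PeriodFold(k, train_idx, test_idx))
    return folds


def mean_fold_auc(per_fold_auc: Sequence[float]) -> float:
    """Cross-fold aggregate: unweighted mean of per-fold AUCs."""
    if not per_fold_auc:
        raise ValueError("no folds")
    return float(np.mean(per_fold_auc))
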
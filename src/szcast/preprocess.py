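"""Recording I/O, seizure bookkeeping, timeline labeling, and STFT segments.

Conventions: 0-based indices, half-open intervals ``[start, end)``, times in
seconds as floats.  Clock times are seconds since a nominal midnight;
hour-of-day is ``(start_clock_s + t) / 3600 mod 24``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft
from scipy.signal import get_window

from . import edfio

logger = logging.getLogger(__name__)

#: Segment length in seconds and default hop (50% overlap).
WINDOW_S = 30.0
#: STFT frame length in seconds (cosine taper, 50% overlap).
FRAME_S = 1.0

Label = Literal["preictal", "interictal", "excluded"]


@dataclass
class EEGRecording:
    """Multichannel EEG signal with sampling metadata.

    ``samples`` has shape ``(n_channels, n_samples)``; ``start_clock_s`` is
    the absolute clock time of sample 0, in seconds since midnight.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_channels, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True, order=True)
class SeizureAnnotation:
    """One annotated seizure: onset/offset in seconds from recording start."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"onset_s ({self.onset_s}) must precede offset_s ({self.offset_s})"
            )


@dataclass(frozen=True)
class LabeledWindow:
    """A 30-s analysis window with its class label and clock hour."""

    start_s: float
    label: Label
    clock_hour: float


@dataclass
class STFTSegment:
    """Trimmed magnitude spectrogram of one window: (n_channels, 56, 128)."""

    values: np.ndarray
    label: Label
    start_s: float
    clock_hour: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[1:] != (56, 128):
            raise ValueError(
                f"values must have shape (n, 56, 128), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


# ---------------------------------------------------------------------------
# Recording I/O


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or a NumPy ``.npz`` array archive.

    The archive format stores ``samples`` (n_channels, n_samples) float array,
    scalar ``sampling_rate``, scalar ``start_clock_s`` and a ``channel_labels``
    string array.  ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "npz"
    format = format.lower().replace("-", "_")
    if format == "edf":
        samples, fs, labels, start_clock_s = edfio.read_edf(path)
        return EEGRecording(samples, fs, labels, start_clock_s)
    if format in ("npz", "array_archive"):
        with np.load(path, allow_pickle=False) as npz:
            for key in ("samples", "sampling_rate"):
                if key not in npz:
                    raise ValueError(f"array archive missing required key {key!r}")
            labels = [str(s) for s in npz["channel_labels"]] if "channel_labels" in npz else []
            start = float(npz["start_clock_s"]) if "start_clock_s" in npz else 0.0
            return EEGRecording(
                npz["samples"], float(npz["sampling_rate"]), labels, start
            )
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(recording: EEGRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as EDF or ``.npz`` (inverse of :func:`read_recording`)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "npz"
    format = format.lower().replace("-", "_")
    if format == "edf":
        edfio.write_edf(
            path,
            recording.samples,
            recording.sampling_rate,
            recording.channel_labels,
            recording.start_clock_s,
        )
    elif format in ("npz", "array_archive"):
        np.savez_compressed(
            path,
            samples=recording.samples,
            sampling_rate=recording.sampling_rate,
            start_clock_s=recording.start_clock_s,
            channel_labels=np.array(recording.channel_labels),
        )
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return path


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read a seizure annotation CSV with ``onset_s`` and ``offset_s`` columns."""
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s"):
        if col not in df.columns:
            raise ValueError(f"annotation CSV missing column {col!r}")
    anns = [
        SeizureAnnotation(float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
    ]
    return sorted(anns)


# ---------------------------------------------------------------------------
# Seizure bookkeeping


def merge_leading_seizures(
    annotations: Sequence[SeizureAnnotation], gap_min: float = 30.0
) -> list[SeizureAnnotation]:
    """Collapse seizure clusters into leading seizures.

    A seizure whose onset is strictly less than ``gap_min`` minutes after the
    previous seizure's onset is absorbed into the running cluster, which
    keeps the leading seizure's onset and extends its offset.  Merging
    chains left-to-right against the most recent cluster member, so a long
    run of closely spaced seizures collapses to one.  A gap of exactly
    ``gap_min`` does NOT merge.
    """
    anns = list(annotations)
    if anns != sorted(anns, key=lambda a: a.onset_s):
        raise ValueError("annotations must be sorted by onset")
    if not anns:
        return []
    gap_s = gap_min * 60.0
    merged: list[SeizureAnnotation] = [anns[0]]
    chain_last_onset = anns[0].onset_s
    for a in anns[1:]:
        prev = merged[-1]
        if a.onset_s - chain_last_onset < gap_s:
            merged[-1] = SeizureAnnotation(prev.onset_s, max(prev.offset_s, a.offset_s))
        else:
            merged.append(a)
        chain_last_onset = a.onset_s
    return merged


def label_timeline(
    recording: EEGRecording,
    leading: Sequence[SeizureAnnotation],
    all_annotations: Sequence[SeizureAnnotation] | None = None,
    preictal_start_min: float = 35.0,
    preictal_end_min: float = 5.0,
    interictal_margin_h: float = 4.0,
) -> list[tuple[tuple[float, float], Label]]:
    """Partition the recording span into preictal/interictal/excluded intervals.

    Preictal is ``[onset - preictal_start_min, onset - preictal_end_min)``
    around each leading seizure; interictal is any time at least
    ``interictal_margin_h`` hours away from every annotated seizure
    (pre-merge annotations when provided, the conservative reading);
    everything else is excluded.
    """
    duration = recording.duration_s
    for s in leading:
        if s.onset_s < 0 or s.onset_s > duration:
            raise ValueError(f"leading seizure at {s.onset_s}s outside recording span")
    return label_intervals(
        duration,
        leading,
        all_annotations=all_annotations,
        preictal_start_min=preictal_start_min,
        preictal_end_min=preictal_end_min,
        interictal_margin_h=interictal_margin_h,
    )


def label_intervals(
    duration_s: float,
    leading: Sequence[SeizureAnnotation],
    all_annotations: Sequence[SeizureAnnotation] | None = None,
    preictal_start_min: float = 35.0,
    preictal_end_min: float = 5.0,
    interictal_margin_h: float = 4.0,
) -> list[tuple[tuple[float, float], Label]]:
    """Signal-free core of :func:`label_timeline` (span given as a duration)."""
    if all_annotations is None:
        all_annotations = leading
    margin_s = interictal_margin_h * 3600.0

    # Preictal windows, later ones truncated when they would overlap.
    preictal: list[tuple[float, float]] = []
    for s in sorted(leading, key=lambda a: a.onset_s):
        lo = max(0.0, s.onset_s - preictal_start_min * 60.0)
        hi = min(duration_s, s.onset_s - preictal_end_min * 60.0)
        if preictal and lo < preictal[-1][1]:
            logger.warning(
                "preictal window starting at %.1fs overlaps previous; truncating", lo
            )
            lo = preictal[-1][1]
        if hi > lo:
            preictal.append((lo, hi))

    # Exclusion zones: within margin of any annotated seizure.
    exclusion = _merge_intervals(
        [
            (max(0.0, a.onset_s - margin_s), min(duration_s, a.offset_s + margin_s))
            for a in all_annotations
        ]
    )

    # Sweep: preictal wins over everything; else interictal iff outside all
    # exclusion zones; else excluded.
    cuts = {0.0, duration_s}
    for lo, hi in preictal + exclusion:
        cuts.update((lo, hi))
    edges = sorted(c for c in cuts if 0.0 <= c <= duration_s)
    out: list[tuple[tuple[float, float], Label]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        mid = 0.5 * (lo + hi)
        if any(a <= mid < b for a, b in preictal):
            lab: Label = "preictal"
        elif any(a <= mid < b for a, b in exclusion):
            lab = "excluded"
        else:
            lab = "interictal"
        if out and out[-1][1] == lab and out[-1][0][1] == lo:
            out[-1] = ((out[-1][0][0], hi), lab)
        else:
            out.append(((lo, hi), lab))
    return out


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(i for i in intervals if i[1] > i[0]):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# Windowing and STFT


def segment_stream(
    recording: EEGRecording,
    intervals: Sequence[tuple[tuple[float, float], Label]] | None = None,
    window_s: float = WINDOW_S,
    overlap: float = 0.5,
) -> list[LabeledWindow]:
    """Slide a ``window_s`` window with the given overlap across the recording.

    Window k starts at ``k * window_s * (1 - overlap)``.  A window wholly
    inside one labeled interval keeps that label; windows straddling interval
    boundaries are excluded.  With ``intervals=None`` all windows are
    interictal (no-seizure convention).
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    duration = recording.duration_s
    if duration < window_s:
        warnings.warn("recording shorter than one window; returning no windows")
        return []
    hop = window_s * (1.0 - overlap)
    n_windows = int(np.floor((duration - window_s) / hop)) + 1
    out: list[LabeledWindow] = []
    for k in range(n_windows):
        start = k * hop
        end = start + window_s
        if intervals is None:
            lab: Label = "interictal"
        else:
            lab = "excluded"
            for (lo, hi), interval_label in intervals:
                if lo <= start and end <= hi:
                    lab = interval_label
                    break
        hour = ((recording.start_clock_s + start) / 3600.0) % 24.0
        out.append(LabeledWindow(start, lab, hour))
    return out


def extract_window(
    recording: EEGRecording, start_s: float, window_s: float = WINDOW_S
) -> np.ndarray:
    """Slice the raw samples of one analysis window: (n_channels, window samples)."""
    i0 = int(round(start_s * recording.sampling_rate))
    i1 = i0 + int(round(window_s * recording.sampling_rate))
    if i0 < 0 or i1 > recording.n_samples:
        raise ValueError("window outside recording span")
    return recording.samples[:, i0:i1]


def compute_stft(
    window: np.ndarray,
    sampling_rate: float = 256.0,
    label: Label = "excluded",
    start_s: float = 0.0,
    clock_hour: float = 0.0,
    log_magnitude: bool = False,
    taper: str = "hann",
) -> STFTSegment:
    """Trimmed magnitude spectrogram of a 30-s window.

    Per channel the mean is removed, the signal is framed into 1-s
    (``sampling_rate``-sample) cosine-tapered frames with 50% overlap (59
    frames at 256 Hz), and the one-sided magnitude spectrum (129 bins) is
    taken.  The first frame and the last two frames are dropped (edge
    disruption; 59 -> 56) and the DC bin is dropped (129 -> 128), giving
    ``(n_channels, 56, 128)``.  ``log_magnitude`` applies ``log1p``.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[None, :]
    frame_len = int(round(FRAME_S * sampling_rate))
    expected = int(round(WINDOW_S * sampling_rate))
    if window.shape[1] != expected:
        raise ValueError(
            f"window must have exactly {expected} samples per channel "
            f"({WINDOW_S:g}s at {sampling_rate:g}Hz), got {window.shape[1]}"
        )
    hop = frame_len // 2
    # Per-channel mean removal: makes the output exactly invariant to constant
    # offsets (the DC bin drop alone would leak through the taper sidelobes).
    window = window - window.mean(axis=1, keepdims=True)
    taper_vals = get_window(taper, frame_len, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(window, frame_len, axis=1)
    frames = frames[:, ::hop, :]  # (n, 59, frame_len)
    spec = np.abs(rfft(frames * taper_vals, axis=2))  # (n, 59, 129)
    spec = spec[:, 1:-2, 1:]  # trim edge frames (59 -> 56) and DC bin (129 -> 128)
    if log_magnitude:
        spec = np.log1p(spec)
    return STFTSegment(spec, label, start_s, clock_hour)


def raw_stft_shape(
    n_samples: int = 7680, frame_len: int = 256
) -> tuple[int, int]:
    """(frames, one-sided bins) of the untrimmed STFT grid for one channel."""
    hop = frame_len // 2
    n_frames = (n_samples - frame_len) // hop + 1
    n_bins = frame_len // 2 + 1
    return n_frames, n_bins


def segments_from_recording(
    recording: EEGRecording,
    annotations: Sequence[SeizureAnnotation],
    log_magnitude: bool = True,
    keep_excluded: bool = False,
    max_windows_per_class: int | None = None,
    seed: int = 0,
    **label_kwargs,
) -> list[STFTSegment]:
    """End-to-end: annotations -> leading merge -> labels -> windows -> STFTs.

    ``max_windows_per_class`` subsamples each label class (without
    replacement, seeded) before the STFT, keeping large recordings tractable.
    """
    leading = merge_leading_seizures(sorted(annotations))
    intervals = label_timeline(
        recording, leading, all_annotations=annotations, **label_kwargs
    )
    windows = segment_stream(recording, intervals)
    if max_windows_per_class is not None:
        rng = np.random.default_rng(seed)
        chosen: list[LabeledWindow] = []
        for lab in ("preictal", "interictal", "excluded"):
            group = [w for w in windows if w.label == lab]
            if len(group) > max_windows_per_class:
                idx = rng.choice(len(group), max_windows_per_class, replace=False)
                group = [group[i] for i in sorted(idx)]
            chosen.extend(group)
        windows = sorted(chosen, key=lambda w: w.start_s)
    out = []
    for w in windows:
        if not keep_excluded and w.label == "excluded":
            continue
        seg = compute_stft(
            extract_window(recording, w.start_s),
            recording.sampling_rate,
            label=w.label,
            start_s=w.start_s,
            clock_hour=w.clock_hour,
            log_magnitude=log_magnitude,
        )
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# Segment HDF5 store

_LABEL_CODE = {"interictal": 0, "preictal": 1, "excluded": 2}
_CODE_LABEL = {v: k for k, v in _LABEL_CODE.items()}


def save_segments(segments: Sequence[STFTSegment], path: str | Path) -> Path:
    """Write segments to HDF5 (datasets: values, label, start_s, clock_hour)."""
    import h5py

    if not segments:
        raise ValueError("no segments to save")
    path = Path(path)
    values = np.stack([s.values for s in segments]).astype(np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values)
        f.create_dataset(
            "label", data=np.array([_LABEL_CODE[s.label] for s in segments])
        )
        f.create_dataset("start_s", data=np.array([s.start_s for s in segments]))
        f.create_dataset(
            "clock_hour", data=np.array([s.clock_hour for s in segments])
        )
    return path


def load_segments(path: str | Path) -> list[STFTSegment]:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][:]
        labels = f["label"][:]
        starts = f["start_s"][:]
        hours = f["clock_hour"][:]
    return [
        STFTSegment(v, _CODE_LABEL[int(c)], float(s), float(h))
        for v, c, s, h in zip(values, labels, starts, hours)
    ]


# ---------------------------------------------------------------------------
# Cohort bookkeeping


def load_cohort_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled reference cohort summary table (or a custom CSV)."""
    if path is None:
        path = Path(__file__).parent / "data" / "cohort_summary.csv"
    return pd.read_csv(path)


def dataset_summary(metadata: pd.DataFrame) -> tuple[int, float]:
    """(total leading seizures, total interictal hours) — exact column sums."""
    for col in ("n_leading_seizures", "interictal_hours"):
        if col not in metadata.columns:
            raise ValueError(f"metadata table missing column {col!r}")
    total_leading = int(metadata["n_leading_seizures"].sum())
    total_hours = float(metadata["interictal_hours"].sum())
    return total_leading, round(total_hours, 6)
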
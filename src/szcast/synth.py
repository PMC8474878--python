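"""Synthetic multichannel EEG with controllable preictal spectral signatures.

Background is 1/f-shaped ("pink-ish") noise plus white noise so spectrogram
bins are non-degenerate.  During the preictal window before each seizure the
1-4 Hz band power on a designated channel subset is raised by a configurable
multiplicative factor, mimicking a slow-activity biomarker.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from .preprocess import (
    EEGRecording,
    SeizureAnnotation,
    label_intervals,
    merge_leading_seizures,
)

#: Slow-activity band carrying the synthetic preictal signature (Hz).
PREICTAL_BAND = (1.0, 4.0)


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator."""

    n_channels: int = 19
    sampling_rate: float = 256.0
    duration_s: float = 3600.0
    n_seizures: int = 0
    seizure_hour_distribution: list[tuple[float, float]] = field(
        default_factory=lambda: [(14.0, 1.0)]
    )
    hour_sd: float = 1.0
    preictal_len_min: float = 30.0
    preictal_effect: float = 1.0
    noise_sd: float = 1.0
    seizure_len_s: float = 60.0
    min_gap_min: float = 120.0
    start_clock_s: float = 0.0
    affected_channels: list[int] | None = None
    n_patients: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.preictal_effect < 1.0:
            raise ValueError("preictal_effect must be >= 1")
        if self.n_seizures < 0:
            raise ValueError("n_seizures must be >= 0")
        w = sum(w for _, w in self.seizure_hour_distribution)
        if self.seizure_hour_distribution and abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if self.hour_sd <= 0:
            raise ValueError("hour_sd must be positive")

    @property
    def channels_with_signature(self) -> list[int]:
        if self.affected_channels is not None:
            return list(self.affected_channels)
        # Default: first half of the montage carries the signature.
        return list(range(max(1, self.n_channels // 2)))


@dataclass
class GeneratedDataset:
    recordings: list[EEGRecording]
    annotations: list[list[SeizureAnnotation]]
    metadata: pd.DataFrame


def sample_onset_hours(
    config: SynthConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n hour-of-day values from the configured wrapped-normal mixture."""
    if n == 0:
        return np.array([])
    comps = config.seizure_hour_distribution
    means = np.array([m for m, _ in comps])
    weights = np.array([w for _, w in comps])
    idx = rng.choice(len(comps), size=n, p=weights)
    hours = rng.normal(means[idx], config.hour_sd)
    return np.mod(hours, 24.0)


def generate_seizure_schedule(config: SynthConfig) -> list[SeizureAnnotation]:
    """Place seizures whose onset clock hours follow the configured mixture.

    Onsets are placed at the earliest occurrence of each drawn clock hour that
    respects the configured minimum inter-seizure gap; raises if the recording
    is too short to hold the requested number of seizures.
    """
    if config.n_seizures == 0:
        return []
    rng = np.random.default_rng(config.seed)
    hours = sample_onset_hours(config, config.n_seizures, rng)
    gap_s = config.min_gap_min * 60.0
    out: list[SeizureAnnotation] = []
    cursor = config.preictal_len_min * 60.0  # room for the first preictal window
    # First occurrence of each drawn clock hour, sorted so several seizures
    # can share one day when the gap allows it.
    bases = np.sort((hours * 3600.0 - config.start_clock_s) % 86400.0)
    for base in bases:
        # Earliest time >= cursor whose clock hour matches the draw.
        onset = base + 86400.0 * np.ceil((cursor - base) / 86400.0)
        offset = onset + config.seizure_len_s
        if offset > config.duration_s:
            raise ValueError(
                f"duration {config.duration_s}s too short to place "
                f"{config.n_seizures} seizures with min gap {config.min_gap_min} min"
            )
        out.append(SeizureAnnotation(float(onset), float(offset)))
        cursor = offset + gap_s
    return out


def _pink_noise(n: int, rng: np.random.Generator, fs: float) -> np.ndarray:
    """Unit-variance noise with a 1/f-shaped amplitude spectrum above 0.5 Hz."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 0.5))
    shaping[0] = 0.0
    x = irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    n: int, rng: np.random.Generator, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` Hz (FFT brick wall)."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    x = irfft(spec * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def band_power(x: np.ndarray, fs: float, band: tuple[float, float] = PREICTAL_BAND) -> float:
    """In-band variance of a 1-D signal via the FFT periodogram."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(rfft(x - x.mean())) ** 2
    f = rfftfreq(x.size, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    return 2.0 * spec[mask].sum() / x.size**2


def generate_recording(
    config: SynthConfig, schedule: list[SeizureAnnotation]
) -> EEGRecording:
    """Synthesize the multichannel signal realizing the given schedule."""
    for s in schedule:
        if s.offset_s > config.duration_s:
            raise ValueError("schedule extends beyond configured duration")
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = np.empty((config.n_channels, n), dtype=np.float32)
    for ch in range(config.n_channels):
        bg = 0.8 * _pink_noise(n, rng, fs) + 0.2 * rng.standard_normal(n)
        samples[ch] = config.noise_sd * bg

    if config.preictal_effect > 1.0:
        for s in schedule:
            lo = int(round(max(0.0, s.onset_s - config.preictal_len_min * 60.0) * fs))
            hi = int(round(s.onset_s * fs))
            if hi <= lo:
                continue
            for ch in config.channels_with_signature:
                seg = samples[ch, lo:hi].astype(float)
                p_bg = band_power(seg, fs)
                extra_var = (config.preictal_effect - 1.0) * p_bg
                boost = _band_noise(hi - lo, rng, fs, PREICTAL_BAND)
                samples[ch, lo:hi] = seg + np.sqrt(extra_var) * boost
    return EEGRecording(
        samples,
        fs,
        [f"ch{i}" for i in range(config.n_channels)],
        config.start_clock_s,
    )


def generate_metadata_table(config: SynthConfig) -> pd.DataFrame:
    """Per-patient bookkeeping: seizure counts, leading counts, interictal hours."""
    rows = []
    for p in range(config.n_patients):
        cfg = SynthConfig(**{**config.__dict__, "seed": config.seed + p})
        schedule = generate_seizure_schedule(cfg)
        leading = merge_leading_seizures(schedule)
        intervals = label_intervals(
            cfg.duration_s, leading, all_annotations=schedule
        )
        inter_h = sum(
            hi - lo for (lo, hi), lab in intervals if lab == "interictal"
        ) / 3600.0
        rows.append(
            {
                "patient": f"Synth{p + 1}",
                "n_seizures": len(schedule),
                "n_leading_seizures": len(leading),
                "interictal_hours": round(inter_h, 1),
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig) -> GeneratedDataset:
    """One recording + schedule per synthetic patient, plus the metadata table."""
    recordings, annotations = [], []
    for p in range(config.n_patients):
        cfg = SynthConfig(**{**config.__dict__, "seed": config.seed + p})
        schedule = generate_seizure_schedule(cfg)
        recordings.append(generate_recording(cfg, schedule))
        annotations.append(schedule)
    return GeneratedDataset(recordings, annotations, generate_metadata_table(config))
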
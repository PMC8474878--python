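"""Minimal EDF (European Data Format, 16-bit) reader/writer.

Supports the plain-EDF subset this package emits: identical sampling rate on
every signal, 1-s data records, no annotations channel.  Start clock time is
carried in the header's starttime field (whole seconds since midnight).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_HDR = 256  # bytes, fixed header
_SIG = 256  # bytes per signal header


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    sampling_rate: float,
    channel_labels: list[str],
    start_clock_s: float = 0.0,
) -> Path:
    samples = np.asarray(samples, dtype=float)
    n_ch, n_samp = samples.shape
    fs = int(round(sampling_rate))
    if fs != sampling_rate:
        raise ValueError("EDF writer supports integer sampling rates only")
    n_records = n_samp // fs
    if n_records * fs != n_samp:
        raise ValueError("signal length must be a whole number of seconds")

    phys_min = samples.min(axis=1)
    phys_max = samples.max(axis=1)
    # Guard degenerate (constant) channels against zero dynamic range.
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    t = int(round(start_clock_s)) % 86400
    hh, mm, ss = t // 3600, (t // 60) % 60, t % 60

    hdr = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # patient id
            _field("Startdate 01-JAN-2000", 80),  # recording id
            _field("01.01.00", 8),
            _field(f"{hh:02d}.{mm:02d}.{ss:02d}", 8),
            _field(str(_HDR + _SIG * n_ch), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )
    sig_hdr = b"".join(
        [
            b"".join(_field(lab, 16) for lab in channel_labels),
            b"".join(_field("EEG", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_min),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_max),
            b"".join(_field(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(_field(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(fs), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    # Re-read the formatted physical extrema so quantization round-trips.
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.clip(
        np.round((samples - pmin[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr)
        f.write(sig_hdr)
        rec = digital.reshape(n_ch, n_records, fs)
        for r in range(n_records):
            f.write(rec[:, r, :].tobytes())
    return Path(path)


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str], float]:
    """Return (samples, sampling_rate, channel_labels, start_clock_s)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise ValueError(f"{path}: too short to be an EDF file")

    def s(lo: int, n: int) -> str:
        return raw[lo : lo + n].decode("ascii", errors="replace").strip()

    try:
        n_records = int(s(236, 8))
        record_dur = float(s(244, 8))
        n_ch = int(s(252, 4))
    except ValueError as e:
        raise ValueError(f"{path}: malformed EDF header") from e
    if n_ch < 1:
        raise ValueError(f"{path}: no signals in header")

    tt = s(176, 8).replace(":", ".").split(".")
    start_clock_s = float(int(tt[0]) * 3600 + int(tt[1]) * 60 + int(tt[2]))

    base = _HDR
    labels = [s(base + 16 * i, 16) for i in range(n_ch)]
    off = base + n_ch * (16 + 80 + 8)
    pmin = np.array([float(s(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    pmax = np.array([float(s(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dmin = np.array([float(s(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dmax = np.array([float(s(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * (8 + 80)
    ns = [int(s(off + 8 * i, 8)) for i in range(n_ch)]
    if len(set(ns)) != 1:
        raise ValueError(f"{path}: per-signal sample counts differ; unsupported")
    spr = ns[0]
    if record_dur <= 0:
        raise ValueError(f"{path}: missing record duration (sampling rate unknown)")
    fs = spr / record_dur

    data_start = _HDR + _SIG * n_ch
    payload = np.frombuffer(raw, dtype="<i2", offset=data_start)
    expect = n_records * n_ch * spr
    if payload.size < expect:
        raise ValueError(f"{path}: truncated data section")
    digital = payload[:expect].reshape(n_records, n_ch, spr)
    digital = digital.transpose(1, 0, 2).reshape(n_ch, n_records * spr)

    scale = (pmax - pmin) / (dmax - dmin)
    samples = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return samples, fs, labels, start_clock_s
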
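"""Recording and schedule containers plus file I/O.

Two on-disk formats are supported for recordings:

* ``delimited`` — plain text CSV: one header row of channel labels, then one
  row per sample (samples are rows so files stream naturally). Lossless for
  float data at the printed precision.
* ``edf`` — European Data Format (16-bit integer samples with per-signal
  physical scaling). Written with a single data record holding the whole
  recording; values survive a round trip to within the quantization step of
  the physical range.

Stimulus schedules are plain text, one onset sample index per line, with a
``# stim_duration=<samples>`` header line.

Sample indexing is 0-based and half-open everywhere in this package.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "StimulusSchedule",
    "SessionPair",
    "EMOTIV_MONTAGE",
    "read_recording",
    "write_recording",
    "read_schedule",
    "write_schedule",
]

#: 10–20 positions of the 14-channel consumer headset montage used throughout.
EMOTIV_MONTAGE = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


@dataclass
class EEGRecording:
    """Multi-channel EEG, ``data`` in microvolts, shape (n_channels, n_samples)."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_channels, n_samples) array")
        if self.data.shape[0] < 2:
            raise ValueError(
                f"a recording needs at least 2 channels, got {self.data.shape[0]}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.sampling_rate, self.channel_labels)


@dataclass
class StimulusSchedule:
    """Stimulus onsets as 0-based sample indices plus a common duration in samples."""

    onsets: np.ndarray
    stim_duration: int

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.onsets.ndim != 1 or self.onsets.size == 0:
            raise ValueError("onsets must be a non-empty 1-D sequence")
        if np.any(self.onsets < 0):
            raise ValueError("onsets must be non-negative sample indices")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("non-monotone onsets: onsets must be strictly increasing")
        self.stim_duration = int(self.stim_duration)
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be a positive sample count")

    @property
    def n_stimuli(self) -> int:
        return int(self.onsets.size)


@dataclass
class SessionPair:
    """A simultaneously recorded sender/receiver session sharing one schedule.

    ``max_skew`` documents the clock skew between the two recordings in
    seconds; the acquisition design guarantees ≤ 8 ms for conforming sessions.
    """

    sender: EEGRecording
    receiver: EEGRecording
    schedule: StimulusSchedule
    pair_id: str = ""
    max_skew: float = 0.008

    def __post_init__(self) -> None:
        if self.sender.sampling_rate != self.receiver.sampling_rate:
            raise ValueError("sender and receiver must share a sampling rate")
        if self.max_skew > 0.008:
            raise ValueError(
                f"pair {self.pair_id!r}: clock skew {self.max_skew}s exceeds the 8 ms bound"
            )


# ---------------------------------------------------------------------------
# delimited text format

def _read_delimited(path: Path) -> EEGRecording:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # ragged rows, empty file, ...
        raise ValueError(f"cannot parse delimited recording {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: a recording needs at least 2 channels")
    labels = tuple(frame.columns)
    rate_attr = None
    # sampling rate travels in a commented first line "# sampling_rate=<hz>"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        raise ValueError(f"{path}: unexpected comment line; rate header unsupported here")
    sidecar = path.with_suffix(path.suffix + ".meta")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if line.startswith("sampling_rate="):
                rate_attr = float(line.split("=", 1)[1])
    if rate_attr is None:
        raise ValueError(
            f"{path}: missing sampling rate (expected sidecar {sidecar.name} "
            "with a 'sampling_rate=' line)"
        )
    return EEGRecording(frame.to_numpy(dtype=float).T, rate_attr, labels)


def _write_delimited(rec: EEGRecording, path: Path) -> None:
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    frame.to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text(f"sampling_rate={rec.sampling_rate:.10g}\n")


# ---------------------------------------------------------------------------
# EDF (European Data Format), minimal but conformant subset

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    out = value.encode("ascii")
    if len(out) > width:
        out = out[:width]
    return out.ljust(width)


def _write_edf(rec: EEGRecording, path: Path) -> None:
    ns = rec.n_channels
    n_samples = rec.n_samples
    # one data record spanning the whole file keeps the layout trivial and exact
    record_dur = n_samples / rec.sampling_rate
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + ns)), 8),
        _edf_field("", 44),
        _edf_field("1", 8),                       # number of data records
        _edf_field(f"{record_dur:.8g}"[:8], 8),   # record duration, seconds
        _edf_field(str(ns), 4),
    ])
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # guard degenerate constant channels: give them a unit physical span
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    per_signal = b"".join([
        b"".join(_edf_field(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_min),
        b"".join(_edf_field(f"{v:.8g}"[:8], 8) for v in phys_max),
        b"".join(_edf_field(str(_EDF_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_edf_field(str(_EDF_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(str(n_samples), 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    # re-read the truncated ASCII physical bounds so scaling matches the header
    pmin_hdr = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax_hdr = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    span = pmax_hdr - pmin_hdr
    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / span
    digital = np.rint((rec.data - pmin_hdr[:, None]) * gain[:, None]) + _EDF_DIG_MIN
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(digital.tobytes())  # channel-sequential within the single record


def _read_edf(path: Path) -> EEGRecording:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")
    header_bytes = int(raw[184:192].decode("ascii").strip())
    n_records = int(raw[236:244].decode("ascii").strip())
    record_dur = float(raw[244:252].decode("ascii").strip())
    ns = int(raw[252:256].decode("ascii").strip())

    def fields(offset: int, width: int) -> list[str]:
        base = 256 + offset * ns
        return [
            raw[base + i * width: base + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    labels = fields(0, 16)
    pmin = np.array([float(v) for v in fields(104, 8)])
    pmax = np.array([float(v) for v in fields(112, 8)])
    dmin = np.array([float(v) for v in fields(120, 8)])
    dmax = np.array([float(v) for v in fields(128, 8)])
    nsamp = np.array([int(v) for v in fields(216, 8)])
    if len(set(nsamp.tolist())) != 1:
        raise ValueError(f"{path}: ragged channel lengths {sorted(set(nsamp.tolist()))}")
    spr = int(nsamp[0])
    body = np.frombuffer(raw[header_bytes:], dtype="<i2")
    expected = n_records * ns * spr
    if body.size < expected:
        raise ValueError(f"{path}: EDF body shorter than header promises")
    body = body[:expected].reshape(n_records, ns, spr).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = np.concatenate(
        [(body[r] - dmin[:, None]) * gain[:, None] + pmin[:, None] for r in range(n_records)],
        axis=1,
    )
    if record_dur <= 0:
        raise ValueError(f"{path}: missing record duration (sampling rate unrecoverable)")
    rate = spr / record_dur
    return EEGRecording(data, rate, tuple(labels))


# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str = "delimited") -> EEGRecording:
    """Read an :class:`EEGRecording`; ``format`` is ``"delimited"`` or ``"edf"``.

    Channel order and sample order are preserved exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    if format == "delimited":
        return _read_delimited(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown recording format {format!r} (use 'delimited' or 'edf')")


def write_recording(rec: EEGRecording, path: str | Path, format: str = "delimited") -> Path:
    """Write ``rec`` so that :func:`read_recording` round-trips it.

    Delimited output is exact to 10 significant digits; EDF quantizes to the
    16-bit step of each channel's physical range.
    """
    path = Path(path)
    if format == "delimited":
        _write_delimited(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r} (use 'delimited' or 'edf')")
    return path


def read_schedule(path: str | Path) -> StimulusSchedule:
    """Read a stimulus schedule (one onset per line; ordering is validated, never repaired)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such schedule file: {path}")
    duration = None
    onsets: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "stim_duration=" in line:
                duration = int(line.split("stim_duration=", 1)[1])
            continue
        try:
            value = int(line)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: onset {line!r} is not an integer") from exc
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative onset {value}")
        onsets.append(value)
    if duration is None:
        raise ValueError(f"{path}: missing '# stim_duration=' header")
    return StimulusSchedule(np.array(onsets), duration)


def write_schedule(sched: StimulusSchedule, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# stim_duration={sched.stim_duration}"]
    lines += [str(int(o)) for o in sched.onsets]
    path.write_text("\n".join(lines) + "\n")
    return path
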
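"""EEG containers, EDF on-disk format, and the preprocessing chain.

The on-disk format is EDF (European Data Format): a 256-byte ASCII header,
one 256-byte ASCII header per signal, then 16-bit little-endian samples in
one-second data records.  Events travel in a tab-separated sidecar file
(``<stem>.events.tsv``) with 0-based onset samples and half-open
``[onset, onset + duration)`` spans, because EDF+ annotation dialects are
not interoperable enough to round-trip reliably.

Preprocessing mirrors a standard resting/ERP recipe: zero-phase Butterworth
band-pass, re-reference to the average of the two mastoids, and deterministic
peak-to-peak artifact rejection on epoched data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "Event",
    "Recording",
    "EpochSet",
    "RejectionRecord",
    "read_edf",
    "write_edf",
    "bandpass",
    "rereference_mastoids",
    "reject_epochs",
]

EDF_DIGITAL_MAX = 32767
EDF_DIGITAL_MIN = -32768


class FormatError(ValueError):
    """Raised for malformed EDF files or invalid container states."""


@dataclass(frozen=True)
class Event:
    """A labelled span of a recording, in samples."""

    onset_sample: int
    duration_samples: int
    code: str


@dataclass
class Recording:
    """A continuous multichannel EEG recording in microvolts.

    ``data`` is channels x samples.  ``reference_state`` tracks whether the
    mastoid re-reference has been applied so it cannot be applied twice.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    events: list[Event] = field(default_factory=list)
    reference_state: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n = self.data.shape[1]
        for ev in self.events:
            if not (0 <= ev.onset_sample < n):
                raise ValueError(f"event onset {ev.onset_sample} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class EpochSet:
    """Fixed-length, time-locked EEG segments.

    ``data`` is epochs x channels x samples.  ``time_origin_ms`` is the time
    of the first sample relative to the lock event (0 for spontaneous
    segments, -200 for stimulus-locked ERP epochs).  ``rejected_flags`` marks
    epochs excluded by artifact rejection; flagged epochs are retained in the
    array so rejection is non-destructive.  For task epochs, ``conditions``
    and ``correct`` carry per-epoch trial metadata.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    condition_label: str | None = None
    time_origin_ms: float = 0.0
    rejected_flags: np.ndarray | None = None
    conditions: np.ndarray | None = None
    correct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.rejected_flags is None:
            self.rejected_flags = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.rejected_flags = np.asarray(self.rejected_flags, dtype=bool)
        if self.rejected_flags.shape[0] != self.data.shape[0]:
            raise ValueError("rejected_flags length must equal epoch count")
        if self.conditions is not None:
            self.conditions = np.asarray(self.conditions)
            if self.conditions.shape[0] != self.data.shape[0]:
                raise ValueError("conditions length must equal epoch count")
        if self.correct is not None:
            self.correct = np.asarray(self.correct, dtype=bool)
            if self.correct.shape[0] != self.data.shape[0]:
                raise ValueError("correct length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected_flags).sum())

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return self.time_origin_ms + step * np.arange(self.data.shape[2])

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None


@dataclass(frozen=True)
class RejectionRecord:
    epoch_index: int
    channel: str
    peak_to_peak_uv: float


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def events_sidecar_path(edf_path: str | Path) -> Path:
    p = Path(edf_path)
    return p.with_name(p.stem + ".events.tsv")


def write_events(events: list[Event], path: str | Path) -> None:
    lines = ["onset_sample\tduration_samples\tcode"]
    for ev in events:
        lines.append(f"{ev.onset_sample}\t{ev.duration_samples}\t{ev.code}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path: str | Path) -> list[Event]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["onset_sample", "duration_samples", "code"]:
        raise FormatError(f"bad events sidecar header in {path}")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        onset, dur, code = line.split("\t")
        out.append(Event(int(onset), int(dur), code))
    return out


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF file plus an events sidecar.

    One data record holds one second of data, so the recording must span a
    whole number of seconds and the sampling rate must be an integer.
    Physical range is symmetric and chosen from the data, so quantization
    error is at most ``physical_range / 2**16``.
    """
    fs = recording.sampling_rate
    if fs != int(fs):
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per record per signal
    n_ch, n_samp = recording.data.shape
    if n_samp % spr != 0:
        raise FormatError(
            f"recording length {n_samp} is not a whole number of 1 s records at {spr} Hz"
        )
    n_rec = n_samp // spr

    peak = float(np.max(np.abs(recording.data))) if n_samp else 0.0
    phys = max(np.ceil(peak), 1.0)  # symmetric physical range, μV

    header = b"".join(
        [
            _pad("0", 8),  # version
            _pad("X X X X", 80),  # patient id (anonymous)
            _pad(f"Startdate X X X X ref:{recording.reference_state}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),  # reserved ("" = plain EDF)
            _pad(str(n_rec), 8),
            _pad("1", 8),  # record duration, seconds
            _pad(str(n_ch), 4),
        ]
    )
    sig = b"".join(_pad(lbl, 16) for lbl in recording.channel_labels)
    sig += b"".join(_pad("AgAgCl electrode", 80) for _ in range(n_ch))
    sig += b"".join(_pad("uV", 8) for _ in range(n_ch))
    sig += b"".join(_pad(f"{-phys:g}", 8) for _ in range(n_ch))
    sig += b"".join(_pad(f"{phys:g}", 8) for _ in range(n_ch))
    sig += b"".join(_pad(str(EDF_DIGITAL_MIN), 8) for _ in range(n_ch))
    sig += b"".join(_pad(str(EDF_DIGITAL_MAX), 8) for _ in range(n_ch))
    sig += b"".join(_pad("", 80) for _ in range(n_ch))  # prefiltering
    sig += b"".join(_pad(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_pad("", 32) for _ in range(n_ch))  # reserved

    scale = (EDF_DIGITAL_MAX - EDF_DIGITAL_MIN) / (2.0 * phys)
    digital = np.rint((recording.data + phys) * scale + EDF_DIGITAL_MIN)
    digital = np.clip(digital, EDF_DIGITAL_MIN, EDF_DIGITAL_MAX).astype("<i2")
    # records x channels x samples-per-record, channel-major inside a record
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(np.ascontiguousarray(records).tobytes())

    write_events(recording.events, events_sidecar_path(path))


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (plain EDF, 1 s records).

    The events sidecar is loaded when present; a missing sidecar yields an
    empty event list.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")

    def fld(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", "replace").strip()

    try:
        header_bytes = int(fld(184, 8))
        n_rec = int(fld(236, 8))
        rec_dur = float(fld(244, 8))
        n_ch = int(fld(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: corrupt EDF header ({exc})") from exc
    if header_bytes != 256 * (1 + n_ch):
        raise FormatError(f"{path}: header length field inconsistent with channel count")
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: truncated signal headers")

    def sig_fld(base: int, width: int, idx: int) -> str:
        off = 256 + base * n_ch + idx * width
        return raw[off : off + width].decode("ascii", "replace").strip()

    labels = [sig_fld(0, 16, i) for i in range(n_ch)]
    phys_min = [float(sig_fld(16 + 80 + 8, 8, i)) for i in range(n_ch)]
    phys_max = [float(sig_fld(16 + 80 + 8 + 8, 8, i)) for i in range(n_ch)]
    dig_min = [int(sig_fld(16 + 80 + 8 + 16, 8, i)) for i in range(n_ch)]
    dig_max = [int(sig_fld(16 + 80 + 8 + 24, 8, i)) for i in range(n_ch)]
    spr = [int(sig_fld(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(n_ch)]

    if len(set(spr)) != 1:
        raise FormatError(f"{path}: mixed per-signal sampling rates {sorted(set(spr))}")
    spr0 = spr[0]
    fs = spr0 / rec_dur

    n_vals = n_rec * n_ch * spr0
    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes, count=n_vals)
    if body.size != n_vals:
        raise FormatError(f"{path}: data section shorter than header declares")
    records = body.reshape(n_rec, n_ch, spr0)
    data = records.transpose(1, 0, 2).reshape(n_ch, n_rec * spr0).astype(np.float64)
    for i in range(n_ch):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (data[i] - dig_min[i]) * gain + phys_min[i]

    ref = "original"
    rec_field = fld(88, 80)
    if "ref:" in rec_field:
        ref = rec_field.split("ref:", 1)[1].split()[0]

    sidecar = events_sidecar_path(path)
    events = read_events(sidecar) if sidecar.exists() else []
    return Recording(data, fs, labels, events, reference_state=ref)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bandpass(recording: Recording, low_hz: float, high_hz: float) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass of every channel.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is squared and no phase distortion is introduced.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=-1)
    return dataclasses.replace(recording, data=filtered, events=list(recording.events))


def rereference_mastoids(
    recording: Recording, mastoid_labels: tuple[str, str] = ("M1", "M2")
) -> Recording:
    """Subtract the mean of the two mastoid channels from every channel.

    Guarded against double application via ``reference_state``.
    """
    if recording.reference_state != "original":
        raise ValueError(
            f"recording already re-referenced (state={recording.reference_state!r})"
        )
    idx = [recording.channel_index(lbl) for lbl in mastoid_labels]
    ref = recording.data[idx].mean(axis=0)
    return dataclasses.replace(
        recording,
        data=recording.data - ref,
        events=list(recording.events),
        reference_state="average_mastoids",
    )


def reject_epochs(
    epochs: EpochSet, peak_to_peak_limit_uv: float
) -> tuple[EpochSet, list[RejectionRecord]]:
    """Flag epochs whose any-channel peak-to-peak amplitude exceeds the limit.

    Flagged epochs stay in the array (``rejected_flags`` is OR-ed with any
    existing flags); retained epochs are untouched.  Returns the flagged set
    and a log of (epoch, worst channel, amplitude) for each new rejection.
    """
    if not peak_to_peak_limit_uv > 0:
        raise ValueError("peak-to-peak limit must be positive")
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)  # epochs x channels
    worst = ptp.argmax(axis=1)
    exceed = ptp.max(axis=1) > peak_to_peak_limit_uv
    log = [
        RejectionRecord(int(i), epochs.channel_labels[worst[i]], float(ptp[i, worst[i]]))
        for i in np.nonzero(exceed & ~epochs.rejected_flags)[0]
    ]
    out = dataclasses.replace(
        epochs,
        rejected_flags=epochs.rejected_flags | exceed,
        data=epochs.data,
    )
    return out, log
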
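"""Resting-state spectral quantification.

Continuous eyes-open/eyes-closed recordings are cut into contiguous 1000 ms
epochs by eye-condition block, turned into a Welch power spectral density
(mean-detrended, Hamming-tapered, zero-padded periodograms averaged across
epochs), and reduced to absolute band powers (μV²) for theta (4–8 Hz),
alpha (8–13 Hz) and beta (13–30 Hz), the theta/beta ratio, and
square-root-transformed versions of alpha power and the ratio.

With the default 1024-point transform at 1000 Hz the frequency grid has the
0.9766 Hz spacing of a zero-padded one-second epoch.  Band edges are
half-open ``[low, high)`` on bin centers, so 8 Hz belongs to alpha and 13 Hz
to beta and no bin is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eegio import EpochSet, Recording

__all__ = [
    "BandDefinition",
    "PowerSpectrum",
    "DEFAULT_BANDS",
    "EYES_OPEN",
    "EYES_CLOSED",
    "segment_spontaneous",
    "welch_psd",
    "band_power",
    "theta_beta_ratio",
    "sqrt_transform",
    "spectral_metrics",
]

EYES_OPEN = "EYES_OPEN"
EYES_CLOSED = "EYES_CLOSED"

ANALYSIS_ELECTRODES = ("Fz", "Cz", "Pz")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, half-open ``[low_hz, high_hz)`` on bin centers."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low {self.low_hz} >= high {self.high_hz}")


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


@dataclass
class PowerSpectrum:
    """Epoch-averaged one-sided power spectral density, μV²/Hz."""

    frequencies_hz: np.ndarray
    power: np.ndarray  # channels x frequencies
    resolution_hz: float
    n_epochs_averaged: int
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        steps = np.diff(self.frequencies_hz)
        if steps.size and not np.allclose(steps, self.resolution_hz, rtol=1e-9):
            raise ValueError("frequency grid spacing must equal resolution_hz")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in spectrum") from None


def segment_spontaneous(
    recording: Recording, epoch_len_ms: float = 1000.0
) -> tuple[EpochSet, EpochSet]:
    """Cut a block-structured resting recording into condition-wise epochs.

    Each ``EYES_OPEN`` / ``EYES_CLOSED`` event spans one block; blocks are cut
    into contiguous, non-overlapping epochs that inherit the block condition,
    so no epoch can straddle a block boundary.  Block durations must be a
    whole multiple of the epoch length.

    Returns ``(eyes_open, eyes_closed)`` epoch sets.
    """
    n_ep_samp = epoch_len_ms * recording.sampling_rate / 1000.0
    if n_ep_samp != int(n_ep_samp):
        raise ValueError("epoch length must be a whole number of samples")
    n_ep_samp = int(n_ep_samp)

    blocks = [ev for ev in recording.events if ev.code in (EYES_OPEN, EYES_CLOSED)]
    if not blocks:
        raise ValueError("recording has no EYES_OPEN / EYES_CLOSED block events")

    per_cond: dict[str, list[np.ndarray]] = {EYES_OPEN: [], EYES_CLOSED: []}
    for ev in blocks:
        if ev.duration_samples % n_ep_samp != 0:
            raise ValueError(
                f"block at sample {ev.onset_sample} spans {ev.duration_samples} samples, "
                f"not a multiple of the {n_ep_samp}-sample epoch"
            )
        stop = ev.onset_sample + ev.duration_samples
        if stop > recording.n_samples:
            raise ValueError(f"block at sample {ev.onset_sample} runs past the recording")
        block = recording.data[:, ev.onset_sample : stop]
        n_ep = ev.duration_samples // n_ep_samp
        # (channels, epochs, samples) -> (epochs, channels, samples)
        per_cond[ev.code].append(
            block.reshape(recording.data.shape[0], n_ep, n_ep_samp).transpose(1, 0, 2)
        )

    def build(code: str, label: str) -> EpochSet:
        chunks = per_cond[code]
        if chunks:
            data = np.concatenate(chunks, axis=0)
        else:
            data = np.empty((0, recording.data.shape[0], n_ep_samp))
        return EpochSet(
            data,
            recording.sampling_rate,
            list(recording.channel_labels),
            condition_label=label,
        )

    return build(EYES_OPEN, "eyes_open"), build(EYES_CLOSED, "eyes_closed")


def welch_psd(epochs: EpochSet, n_fft: int = 1024, window: str = "hamming") -> PowerSpectrum:
    """Welch power spectral density with epochs as the averaging segments.

    Per retained epoch: remove the mean, taper, zero-pad to ``n_fft``, and
    form a density-scaled periodogram (taper-power corrected, one-sided);
    then average across epochs.  The default 1024-point grid at 1000 Hz gives
    1000/1024 = 0.9766 Hz resolution.
    """
    n_samp = epochs.data.shape[2]
    if n_fft < n_samp:
        raise ValueError(f"n_fft ({n_fft}) must be >= epoch length ({n_samp})")
    keep = ~epochs.rejected_flags
    if not keep.any():
        raise ValueError("all epochs rejected; nothing to average")
    data = epochs.data[keep]  # epochs x channels x samples

    fs = epochs.sampling_rate
    win = sps.get_window(window, n_samp, fftbins=True)
    detrended = data - data.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(detrended * win, n=n_fft, axis=-1)
    # density scaling with taper-power correction; one-sided doubling
    pxx = (np.abs(spec) ** 2) / (fs * np.sum(win**2))
    if n_fft % 2 == 0:
        pxx[..., 1:-1] *= 2.0  # keep DC and Nyquist single-sided
    else:
        pxx[..., 1:] *= 2.0
    power = pxx.mean(axis=0)

    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return PowerSpectrum(
        frequencies_hz=freqs,
        power=power,
        resolution_hz=fs / n_fft,
        n_epochs_averaged=int(keep.sum()),
        channel_labels=list(epochs.channel_labels),
    )


def band_power(spectrum: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Absolute band power per channel, μV².

    Rectangle integration: sum of density over bins whose center lies in
    ``[low_hz, high_hz)``, times the grid spacing.
    """
    f = spectrum.frequencies_hz
    if band.low_hz < f[0] or band.high_hz > f[-1] + spectrum.resolution_hz:
        raise ValueError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) outside the "
            f"spectrum grid [{f[0]}, {f[-1]}]"
        )
    mask = (f >= band.low_hz) & (f < band.high_hz)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    return spectrum.power[:, mask].sum(axis=1) * spectrum.resolution_hz


def theta_beta_ratio(theta_power, beta_power):
    """Theta band power divided by beta band power (elementwise)."""
    theta_power = np.asarray(theta_power, dtype=np.float64)
    beta_power = np.asarray(beta_power, dtype=np.float64)
    if np.any(beta_power <= 0):
        raise ValueError("beta power must be strictly positive")
    return theta_power / beta_power


def sqrt_transform(value):
    """Principal square root, used to normalize alpha power and the ratio."""
    value = np.asarray(value, dtype=np.float64)
    if np.any(value < 0):
        raise ValueError("square-root transform requires non-negative input")
    return np.sqrt(value)


def spectral_metrics(
    eyes_open: EpochSet,
    eyes_closed: EpochSet,
    electrodes: tuple[str, ...] = ANALYSIS_ELECTRODES,
    bands: dict[str, BandDefinition] | None = None,
    n_fft: int = 1024,
) -> pd.DataFrame:
    """Band powers and theta/beta ratio per eye condition and electrode.

    Returns a tidy frame with one row per (condition, electrode) and columns
    theta_power, alpha_power, beta_power, theta_beta_ratio, alpha_power_sqrt,
    theta_beta_ratio_sqrt.
    """
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    rows = []
    for epochs in (eyes_open, eyes_closed):
        idx = [epochs.channel_index(e) for e in electrodes]
        subset = EpochSet(
            epochs.data[:, idx, :],
            epochs.sampling_rate,
            [epochs.channel_labels[i] for i in idx],
            condition_label=epochs.condition_label,
            time_origin_ms=epochs.time_origin_ms,
            rejected_flags=epochs.rejected_flags,
        )
        spectrum = welch_psd(subset, n_fft=n_fft)
        powers = {name: band_power(spectrum, b) for name, b in bands.items()}
        for el in electrodes:
            ci = spectrum.channel_index(el)
            theta = float(powers["theta"][ci])
            alpha = float(powers["alpha"][ci])
            beta = float(powers["beta"][ci])
            tbr = float(theta_beta_ratio(theta, beta))
            rows.append(
                {
                    "condition": epochs.condition_label,
                    "electrode": el,
                    "theta_power": theta,
                    "alpha_power": alpha,
                    "beta_power": beta,
                    "theta_beta_ratio": tbr,
                    "alpha_power_sqrt": float(sqrt_transform(alpha)),
                    "theta_beta_ratio_sqrt": float(sqrt_transform(tbr)),
                }
            )
    return pd.DataFrame(rows)
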
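"""Flanker ERP quantification.

Stimulus-locked epochs (−200 to 1000 ms), baseline correction over the
pre-stimulus interval, removal of incorrect and artifact-flagged trials,
per-condition averaging, and component mean amplitudes: N2 as the signed
mean at Fz over 230–380 ms, P3 as the signed mean at CPz over 400–600 ms.
Difference scores (N2d, P3d, RT interference) are incongruent minus
congruent throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eegio import EpochSet, Recording

__all__ = [
    "ComponentWindow",
    "ErpAverage",
    "N2_WINDOW",
    "P3_WINDOW",
    "CONDITIONS",
    "epoch_flanker",
    "baseline_correct",
    "select_correct",
    "average_condition",
    "mean_amplitude",
    "difference_scores",
    "erp_metrics",
]

CONDITIONS = ("congruent", "incongruent")

EPOCH_START_MS = -200.0
EPOCH_STOP_MS = 1000.0  # half-open: epoch covers [-200, 1000) ms
BASELINE_MS = (-200.0, 0.0)


@dataclass(frozen=True)
class ComponentWindow:
    """A named measurement window at one electrode, endpoints inclusive."""

    name: str
    electrode: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(f"window {self.name}: start {self.start_ms} >= end {self.end_ms}")


N2_WINDOW = ComponentWindow("N2", "Fz", 230.0, 380.0)
P3_WINDOW = ComponentWindow("P3", "CPz", 400.0, 600.0)


@dataclass
class ErpAverage:
    """Per-condition average waveform, channels x samples, μV."""

    condition: str
    data: np.ndarray
    time_axis_ms: np.ndarray
    channel_labels: list[str]
    n_trials_averaged: int

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in average") from None


def epoch_flanker(
    recording: Recording,
    trials: pd.DataFrame,
    start_ms: float = EPOCH_START_MS,
    stop_ms: float = EPOCH_STOP_MS,
) -> tuple[EpochSet, list[dict]]:
    """Cut one stimulus-locked epoch per trial.

    The window is ``[start_ms, stop_ms)`` relative to each ``onset_sample``
    (1200 samples at 1000 Hz with the defaults).  Trials whose window falls
    outside the recording are excluded, not fatal; each exclusion is logged
    with its trial index and reason.  Epochs carry per-trial condition and
    correctness.
    """
    fs = recording.sampling_rate
    pre = int(round(-start_ms * fs / 1000.0))
    post = int(round(stop_ms * fs / 1000.0))
    n_win = pre + post

    kept_data, kept_cond, kept_corr = [], [], []
    excluded: list[dict] = []
    for row in trials.itertuples(index=False):
        onset = int(row.onset_sample)
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > recording.n_samples:
            excluded.append(
                {
                    "trial_index": int(row.trial_index),
                    "onset_sample": onset,
                    "reason": f"window [{lo}, {hi}) outside recording of {recording.n_samples} samples",
                }
            )
            continue
        kept_data.append(recording.data[:, lo:hi])
        kept_cond.append(row.condition)
        kept_corr.append(bool(row.correct))

    data = (
        np.stack(kept_data)
        if kept_data
        else np.empty((0, recording.data.shape[0], n_win))
    )
    epochs = EpochSet(
        data,
        fs,
        list(recording.channel_labels),
        time_origin_ms=start_ms,
        conditions=np.asarray(kept_cond, dtype=object),
        correct=np.asarray(kept_corr, dtype=bool),
    )
    return epochs, excluded


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float] = BASELINE_MS) -> EpochSet:
    """Subtract the mean over the pre-stimulus interval per epoch and channel.

    The baseline window is half-open ``[start, stop)`` so the stimulus-onset
    sample itself is excluded.
    """
    t = epochs.times_ms
    mask = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not mask.any():
        raise ValueError(f"epochs do not cover the baseline interval {baseline_ms}")
    baseline = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return dataclasses.replace(epochs, data=epochs.data - baseline)


def select_correct(epochs: EpochSet) -> EpochSet:
    """Keep only correct-response, non-rejected epochs.

    Fails loudly if any condition present in the input loses all its epochs,
    since a downstream average over that condition would be undefined.
    """
    if epochs.correct is None:
        raise ValueError("epochs carry no correctness flags")
    keep = epochs.correct & ~epochs.rejected_flags
    for cond in np.unique(epochs.conditions):
        if not keep[epochs.conditions == cond].any():
            raise ValueError(f"no retained epochs left in condition {cond!r}")
    return dataclasses.replace(
        epochs,
        data=epochs.data[keep],
        rejected_flags=epochs.rejected_flags[keep],
        conditions=epochs.conditions[keep],
        correct=epochs.correct[keep],
    )


def average_condition(epochs: EpochSet, condition: str) -> ErpAverage:
    """Pointwise mean across retained epochs of one condition."""
    if epochs.conditions is None:
        raise ValueError("epochs carry no condition labels")
    sel = (epochs.conditions == condition) & ~epochs.rejected_flags
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no retained epochs in condition {condition!r}")
    return ErpAverage(
        condition=condition,
        data=epochs.data[sel].mean(axis=0),
        time_axis_ms=epochs.times_ms,
        channel_labels=list(epochs.channel_labels),
        n_trials_averaged=n,
    )


def mean_amplitude(average: ErpAverage, window: ComponentWindow) -> float:
    """Signed mean amplitude over the component window, μV.

    Endpoints are inclusive on the sample grid (230–380 ms covers samples at
    230, 231, …, 380 ms).  No rectification: N2 values come out negative,
    P3 values positive.
    """
    t = average.time_axis_ms
    if window.start_ms < t[0] or window.end_ms > t[-1]:
        raise ValueError(
            f"window {window.name} [{window.start_ms}, {window.end_ms}] ms outside "
            f"epoch span [{t[0]}, {t[-1]}] ms"
        )
    ci = average.channel_index(window.electrode)
    mask = (t >= window.start_ms) & (t <= window.end_ms)
    return float(average.data[ci, mask].mean())


def difference_scores(
    n2: dict[str, float], p3: dict[str, float], rt: dict[str, float]
) -> tuple[float, float, float]:
    """Incongruent-minus-congruent difference scores (N2d, P3d μV; RT ms)."""
    out = []
    for name, vals in (("N2", n2), ("P3", p3), ("RT", rt)):
        missing = [c for c in CONDITIONS if c not in vals]
        if missing:
            raise ValueError(f"{name}: missing condition value(s) {missing}")
        out.append(vals["incongruent"] - vals["congruent"])
    return tuple(out)  # type: ignore[return-value]


def erp_metrics(
    epochs: EpochSet,
    n2_window: ComponentWindow = N2_WINDOW,
    p3_window: ComponentWindow = P3_WINDOW,
) -> dict[str, float]:
    """Baseline-correct, drop incorrect trials, average, and measure N2/P3.

    Input epochs are raw stimulus-locked cuts (artifact flags already set if
    rejection ran).  Returns per-condition amplitudes plus N2d and P3d.
    """
    corrected = baseline_correct(epochs)
    retained = select_correct(corrected)
    out: dict[str, float] = {}
    for cond in CONDITIONS:
        avg = average_condition(retained, cond)
        out[f"n2_{cond}"] = mean_amplitude(avg, n2_window)
        out[f"p3_{cond}"] = mean_amplitude(avg, p3_window)
        out[f"n_trials_{cond}"] = avg.n_trials_averaged
    out["n2d"] = out["n2_incongruent"] - out["n2_congruent"]
    out["p3d"] = out["p3_incongruent"] - out["p3_congruent"]
    return out
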
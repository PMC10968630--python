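"""Seedable synthetic cohorts with known ground truth.

The generator emulates the study design the analysis pipeline expects:

* a cohort of subjects whose latent measures (ACS total, theta/beta ratio,
  alpha power, flanker RT interference, P3d) follow a requested correlation
  structure, realized through a Gaussian copula over a validated positive
  semi-definite correlation matrix;
* per subject, an 8-minute resting recording alternating one-minute
  eyes-open / eyes-closed blocks, built from 1/f background noise plus
  narrowband theta (4–8 Hz), alpha (8–13 Hz) and beta (13–30 Hz)
  oscillations, with the alpha amplitude multiplied by the subject's
  reactivity factor while the eyes are closed;
* per subject, a flanker-task recording with stimulus-locked N2 and P3
  Gaussian templates (frontal-negative around 300 ms, centro-parietal
  positive around 500 ms) whose window-mean amplitudes are exactly the
  profile's per-condition targets, plus a behavioral trial table with
  truncated-normal RTs and Bernoulli correctness.

Oscillations come in two flavours: ``narrowband`` (band-pass-filtered white
noise, the default — what resting EEG rhythms actually look like) and
``sinusoid`` (pure tones with random phase), the latter existing so that
spectral ground truth is analytic: a tone of amplitude A carries power A²/2.

Seeding is hierarchical: one global seed, split per subject and per stage,
so enlarging the cohort never perturbs already-generated subjects.

Marginal distributions are anchored to published group statistics of the
kind of cohort being emulated (RT means near 466/529 ms, N2 near −1.5/−2.6
μV, P3 near 6.2/7.3 μV, square-root theta/beta ratio near 2.3, square-root
alpha power near 2.0 eyes-open and 4.0 eyes-closed); between-subject SDs
are the printed standard errors scaled by sqrt(58).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal as sps
from scipy import stats as st

from .eegio import Event, Recording
from .spectral import EYES_CLOSED, EYES_OPEN

__all__ = [
    "LATENT_VARS",
    "CHANNELS",
    "MASTOIDS",
    "DEFAULT_TARGET_CORRELATIONS",
    "CohortSpec",
    "SubjectProfile",
    "correlation_matrix",
    "make_cohort",
    "simulate_resting",
    "simulate_flanker",
    "validate_trial_table",
    "profiles_to_frame",
]

#: latent measures that can carry target correlations
LATENT_VARS = (
    "acs_total",
    "theta_beta_ratio_true",
    "alpha_power_true",
    "rt_interference_true",
    "p3d_true",
)

CHANNELS = ["Fz", "Cz", "Pz", "CPz", "M1", "M2"]
MASTOIDS = ("M1", "M2")
_SCALP = [c for c in CHANNELS if c not in MASTOIDS]

#: defaults drawn from the group-level correlation structure being emulated
DEFAULT_TARGET_CORRELATIONS: dict[tuple[str, str], float] = {
    ("acs_total", "theta_beta_ratio_true"): -0.263,
    ("acs_total", "alpha_power_true"): -0.131,
    ("acs_total", "rt_interference_true"): 0.305,
    ("acs_total", "p3d_true"): 0.152,
    ("alpha_power_true", "rt_interference_true"): -0.266,
    ("alpha_power_true", "p3d_true"): 0.285,
    ("rt_interference_true", "p3d_true"): -0.261,
}

# marginal anchors: (mean, between-subject sd)
_TBR_SQRT = (2.33, 0.53)  # sqrt of theta/beta ratio, eyes-open frontal
_ALPHA_SQRT_OPEN = (1.97, 0.60)  # sqrt of alpha power, μV, eyes-open
_ALPHA_REACTIVITY = (2.05, 0.25)  # eyes-closed / eyes-open alpha amplitude
_RT_CONGRUENT = (466.29, 79.8)  # ms
_RT_INTERFERENCE = (62.45, 22.9)  # ms
_ACC_CONGRUENT = (0.9761, 0.0533)
_ACC_DIFF = (0.0508, 0.0877)  # congruent minus incongruent
_N2_CONGRUENT = (-1.54, 4.80)  # μV, window mean at Fz
_N2D = (-1.05, 1.78)
_P3_CONGRUENT = (6.23, 4.04)  # μV, window mean at CPz
_P3D = (1.07, 2.61)
_BETA_POWER_BASE = 2.0  # μV², oscillatory beta band power
_NOISE_RMS = 2.0  # μV, 1/f background
_RT_TRIAL_SD = 60.0  # ms, within-subject trial scatter
_RT_FLOOR = 150.0  # ms, truncation point

_BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
_BAND_CENTER = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}

# ERP template geometry: Gaussian bumps, (peak_ms, sd_ms, measurement window)
_N2_SHAPE = (300.0, 40.0, (230.0, 380.0))
_P3_SHAPE = (500.0, 60.0, (400.0, 600.0))
_N2_TOPOGRAPHY = {"Fz": 1.0, "Cz": 0.8, "CPz": 0.5, "Pz": 0.4}
_P3_TOPOGRAPHY = {"CPz": 1.0, "Pz": 0.9, "Cz": 0.8, "Fz": 0.4}

# flanker trial timing, seconds
_FIXATION_S = 0.300
_BLANK_S = (1.200, 1.600)
_STIMULUS_S = 0.200
_ITI_S = (2.000, 2.400)


class CorrelationSpecError(ValueError):
    """Raised when the requested correlation matrix is not PSD."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one synthetic cohort."""

    n_subjects: int = 58
    target_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS)
    )
    seed: int = 0
    duration_resting_s: float = 480.0
    block_len_s: float = 60.0
    n_trials_per_condition: int = 120
    sampling_rate: float = 1000.0
    oscillation_mode: str = "narrowband"  # or "sinusoid"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration_resting_s <= 0 or self.block_len_s <= 0:
            raise ValueError("durations must be positive")
        if self.oscillation_mode not in ("narrowband", "sinusoid"):
            raise ValueError(f"unknown oscillation mode {self.oscillation_mode!r}")
        for pair, rho in self.target_correlations.items():
            a, b = pair
            for name in pair:
                if name not in LATENT_VARS:
                    raise ValueError(f"unknown latent variable {name!r} in pair {pair}")
            if a == b:
                raise ValueError(f"self-pair {pair} not allowed")
            if not -1 < rho < 1:
                raise ValueError(f"correlation for {pair} must lie in (-1, 1), got {rho}")
        correlation_matrix(self)  # PSD validation at construction


@dataclass
class SubjectProfile:
    """Ground-truth parameters of one synthetic subject."""

    subject_id: str
    subject_index: int
    trait_control: float  # latent standard-normal attentional-control trait
    band_amplitude: dict[str, float]  # μV, sinusoid-equivalent (power A²/2)
    alpha_reactivity: float  # eyes-closed / eyes-open alpha amplitude factor
    noise_scale: float  # μV RMS of the 1/f background
    acs_total: int
    rt_congruent_mean: float  # ms
    rt_interference_true: float  # ms
    rt_trial_sd: float  # ms
    erp_amp: dict[str, float]  # window-mean μV per component x condition
    trial_noise_sd: float  # μV RMS of the flanker background
    accuracy_prob: dict[str, float]
    theta_beta_ratio_true: float
    alpha_power_true: float  # μV², eyes-open alpha band power
    p3d_true: float  # μV

    def __post_init__(self) -> None:
        if self.alpha_reactivity < 1:
            raise ValueError("alpha_reactivity must be >= 1")
        if any(a < 0 for a in self.band_amplitude.values()):
            raise ValueError("band amplitudes must be non-negative")
        if not 20 <= self.acs_total <= 80:
            raise ValueError(f"acs_total {self.acs_total} outside [20, 80]")
        for cond, p in self.accuracy_prob.items():
            if not 0 < p <= 1:
                raise ValueError(f"accuracy_prob[{cond}] = {p} outside (0, 1]")


# ---------------------------------------------------------------------------
# Latent structure
# ---------------------------------------------------------------------------

def _assemble_matrix(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    k = len(LATENT_VARS)
    idx = {name: i for i, name in enumerate(LATENT_VARS)}
    mat = np.eye(k)
    for (a, b), rho in pairs.items():
        mat[idx[a], idx[b]] = rho
        mat[idx[b], idx[a]] = rho
    return mat


def correlation_matrix(spec: CohortSpec) -> np.ndarray:
    """The implied latent correlation matrix; raises if not PSD.

    When the matrix fails, each specified pair is dropped in turn to find
    those whose removal restores positive semi-definiteness, and the error
    names them.
    """
    mat = _assemble_matrix(spec.target_correlations)
    if np.linalg.eigvalsh(mat).min() >= -1e-10:
        return mat
    offending = []
    for pair in spec.target_correlations:
        reduced = {p: r for p, r in spec.target_correlations.items() if p != pair}
        if np.linalg.eigvalsh(_assemble_matrix(reduced)).min() >= -1e-10:
            offending.append(pair)
    raise CorrelationSpecError(
        "target correlation matrix is not positive semi-definite; "
        f"offending pair(s): {offending or sorted(spec.target_correlations)}"
    )


def _latent_cholesky(spec: CohortSpec) -> np.ndarray:
    mat = correlation_matrix(spec)
    # nudge onto the PD cone so Cholesky succeeds at the PSD boundary
    return np.linalg.cholesky(mat + 1e-12 * np.eye(mat.shape[0]))


def _subject_rng(spec: CohortSpec, subject_index: int, stage: int) -> np.random.Generator:
    """Independent stream per (seed, subject, stage); stable under cohort growth."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index, stage))
    return np.random.default_rng(ss)


def make_cohort(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw ``n_subjects`` profiles with the requested latent correlations."""
    chol = _latent_cholesky(spec)
    profiles = []
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec, i, stage=0)
        z = chol @ rng.standard_normal(len(LATENT_VARS))
        u = rng.standard_normal(8)  # independent nuisance marginals
        z_acs, z_tbr, z_alpha, z_rt, z_p3d = z

        acs = int(np.clip(20 + round(60 * st.norm.cdf(z_acs)), 20, 80))
        tbr_sqrt = max(_TBR_SQRT[0] + _TBR_SQRT[1] * z_tbr, 0.5)
        tbr_true = tbr_sqrt**2
        alpha_sqrt = max(_ALPHA_SQRT_OPEN[0] + _ALPHA_SQRT_OPEN[1] * z_alpha, 0.3)
        alpha_power = alpha_sqrt**2
        beta_power = _BETA_POWER_BASE * math.exp(0.15 * u[0])
        theta_power = tbr_true * beta_power
        reactivity = max(_ALPHA_REACTIVITY[0] + _ALPHA_REACTIVITY[1] * u[1], 1.0)
        noise = _NOISE_RMS * math.exp(0.15 * u[2])

        rt_cong = max(_RT_CONGRUENT[0] + _RT_CONGRUENT[1] * u[3], 250.0)
        rt_int = _RT_INTERFERENCE[0] + _RT_INTERFERENCE[1] * z_rt
        acc_cong = float(np.clip(_ACC_CONGRUENT[0] + _ACC_CONGRUENT[1] * u[4], 0.60, 1.0))
        acc_incong = float(
            np.clip(acc_cong - (_ACC_DIFF[0] + _ACC_DIFF[1] * u[5]), 0.30, 1.0)
        )

        n2_cong = _N2_CONGRUENT[0] + _N2_CONGRUENT[1] * u[6]
        n2d = _N2D[0] + _N2D[1] * u[7]
        p3_cong = _P3_CONGRUENT[0] + _P3_CONGRUENT[1] * rng.standard_normal()
        p3d = _P3D[0] + _P3D[1] * z_p3d

        profiles.append(
            SubjectProfile(
                subject_id=f"sub-{i + 1:03d}",
                subject_index=i,
                trait_control=float(z_acs),
                band_amplitude={
                    "theta": math.sqrt(2.0 * theta_power),
                    "alpha": math.sqrt(2.0 * alpha_power),
                    "beta": math.sqrt(2.0 * beta_power),
                },
                alpha_reactivity=float(reactivity),
                noise_scale=float(noise),
                acs_total=acs,
                rt_congruent_mean=float(rt_cong),
                rt_interference_true=float(rt_int),
                rt_trial_sd=_RT_TRIAL_SD,
                erp_amp={
                    "N2_congruent": float(n2_cong),
                    "N2_incongruent": float(n2_cong + n2d),
                    "P3_congruent": float(p3_cong),
                    "P3_incongruent": float(p3_cong + p3d),
                },
                trial_noise_sd=float(noise),
                accuracy_prob={"congruent": acc_cong, "incongruent": acc_incong},
                theta_beta_ratio_true=float(tbr_true),
                alpha_power_true=float(alpha_power),
                p3d_true=float(p3d),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Flatten profiles into one row per subject for export."""
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "trait_control": p.trait_control,
            "acs_total": p.acs_total,
            "alpha_reactivity": p.alpha_reactivity,
            "noise_scale": p.noise_scale,
            "rt_congruent_mean": p.rt_congruent_mean,
            "rt_interference_true": p.rt_interference_true,
            "rt_trial_sd": p.rt_trial_sd,
            "trial_noise_sd": p.trial_noise_sd,
            "theta_beta_ratio_true": p.theta_beta_ratio_true,
            "alpha_power_true": p.alpha_power_true,
            "p3d_true": p.p3d_true,
        }
        row.update({f"amp_{k}": v for k, v in p.band_amplitude.items()})
        row.update({f"erp_{k}": v for k, v in p.erp_amp.items()})
        row.update({f"acc_{k}": v for k, v in p.accuracy_prob.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------
#
# Noise and narrowband rhythms are synthesized spectrally: complex Gaussian
# spectra shaped by the target amplitude response, normalized to the exact
# target RMS through Parseval's identity, and inverse-FFT'd in one batch.
# For Gaussian noise this is equivalent to filtering white noise with the
# same response, at a fraction of the cost.


@lru_cache(maxsize=32)
def _butter_band_gain(low: float, high: float, nf: int, fs: float) -> np.ndarray:
    """|H(f)| of the 4th-order Butterworth band-pass on an rfft grid."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    freqs = np.linspace(0.0, fs / 2.0, nf)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.abs(h)
    gain.setflags(write=False)
    return gain


def _pink_gain(nf: int, n_samples: int, fs: float, f_min: float = 0.5) -> np.ndarray:
    """1/sqrt(f) spectral shaping (power ~ 1/f), flat below ``f_min``, no DC."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros(nf)
    nz = freqs > 0
    gain[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], f_min))
    return gain


def _synth_series(
    rng: np.random.Generator,
    gains: np.ndarray,
    target_rms: np.ndarray,
    n_samples: int,
    rms_masks: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Batch of Gaussian series with given spectral shapes and exact RMS.

    ``gains`` is (k, nf); each row shapes one series.  The DC bin is zeroed,
    so every series is exactly zero-mean and Parseval gives its RMS in
    closed form before the inverse transform.  ``rms_masks`` optionally
    restricts row i's RMS normalization to a boolean frequency mask, so a
    band-limited carrier can be scaled by its in-band power rather than its
    total power (the filter skirts carry a few percent of the energy).
    """
    k, nf = gains.shape
    draws = rng.standard_normal((2, k, nf), dtype=np.float32)
    spec = (draws[0] + 1j * draws[1]).astype(np.complex128)
    spec *= gains
    spec[:, 0] = 0.0
    if n_samples % 2 == 0:
        spec[:, -1] = spec[:, -1].real  # irfft ignores the Nyquist imaginary part
    # irfft Parseval: sum x^2 = (2 sum|X|^2 - |X_0|^2 - |X_nyq|^2) / n
    power = spec.real**2 + spec.imag**2
    energy = 2.0 * power.sum(axis=1)
    if n_samples % 2 == 0:
        energy -= power[:, -1]
    if rms_masks:
        for i, mask in rms_masks.items():
            energy[i] = 2.0 * power[i, mask].sum()
    rms = np.sqrt(energy) / n_samples
    scale = np.divide(
        np.asarray(target_rms, dtype=np.float64), rms,
        out=np.zeros(k), where=rms > 0,
    )
    spec *= scale[:, None]
    return sfft.irfft(spec, n=n_samples, axis=-1)


def _sinusoid(rng: np.random.Generator, band: str, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS pure tone at the band's center frequency, random phase."""
    t = np.arange(n_samples) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * _BAND_CENTER[band] * t + phase)


_BAND_ORDER = ("theta", "alpha", "beta")


def _ongoing_signals(
    rng: np.random.Generator,
    profile: SubjectProfile,
    n_samples: int,
    fs: float,
    mode: str,
    noise_rms: float,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-channel background noise and coherent band rhythms.

    Returns ``(noise, rhythms)`` where ``noise`` is (n_channels, n) of 1/f
    background at ``noise_rms`` RMS and ``rhythms`` maps each band to one
    series shared across scalp channels whose RMS is the sinusoid-equivalent
    A/sqrt(2) for the profile's amplitude A.  The random stream layout is
    fixed (all bands are always drawn), so a zero-amplitude band does not
    shift any other component's realization.
    """
    nf = n_samples // 2 + 1
    n_ch = len(CHANNELS)
    band_rms = {
        b: profile.band_amplitude.get(b, 0.0) / math.sqrt(2.0) for b in _BAND_ORDER
    }
    if mode == "narrowband":
        gains = np.empty((n_ch + len(_BAND_ORDER), nf))
        gains[:n_ch] = _pink_gain(nf, n_samples, fs)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        masks: dict[int, np.ndarray] = {}
        for j, b in enumerate(_BAND_ORDER):
            lo, hi = _BAND_EDGES[b]
            gains[n_ch + j] = _butter_band_gain(lo, hi, nf, fs)
            masks[n_ch + j] = (freqs >= lo) & (freqs < hi)
        targets = np.concatenate(
            [np.full(n_ch, noise_rms), [band_rms[b] for b in _BAND_ORDER]]
        )
        series = _synth_series(rng, gains, targets, n_samples, rms_masks=masks)
        return series[:n_ch], {b: series[n_ch + j] for j, b in enumerate(_BAND_ORDER)}
    gains = np.ascontiguousarray(
        np.broadcast_to(_pink_gain(nf, n_samples, fs), (n_ch, nf))
    )
    noise = _synth_series(rng, gains, np.full(n_ch, noise_rms), n_samples)
    rhythms = {b: band_rms[b] * _sinusoid(rng, b, n_samples, fs) for b in _BAND_ORDER}
    return noise, rhythms


# ---------------------------------------------------------------------------
# Resting-state simulation
# ---------------------------------------------------------------------------

def simulate_resting(profile: SubjectProfile, spec: CohortSpec) -> Recording:
    """One resting recording with alternating eye-condition blocks.

    Eyes-open comes first.  Oscillations are coherent across the four scalp
    channels; mastoids carry only attenuated background noise so that the
    average-mastoid re-reference does not cancel the signals of interest.
    A band amplitude A (μV) yields band power A²/2 (μV²), exactly so in
    ``sinusoid`` mode and in expectation in ``narrowband`` mode; while the
    eyes are closed, the alpha amplitude is multiplied by
    ``alpha_reactivity``.
    """
    fs = spec.sampling_rate
    n_total = spec.duration_resting_s * fs
    n_block = spec.block_len_s * fs
    if n_total <= 0:
        raise ValueError("zero-length recording requested")
    if n_total != int(n_total) or n_block != int(n_block):
        raise ValueError("durations must be whole numbers of samples")
    n_total, n_block = int(n_total), int(n_block)
    if n_total % n_block != 0:
        raise ValueError(
            f"resting duration {spec.duration_resting_s}s is not a whole multiple "
            f"of the {spec.block_len_s}s block length"
        )
    n_blocks = n_total // n_block

    rng = _subject_rng(spec, profile.subject_index, stage=1)
    # alpha gain: 1 in eyes-open blocks, reactivity in eyes-closed blocks
    block_codes = [EYES_OPEN if b % 2 == 0 else EYES_CLOSED for b in range(n_blocks)]
    alpha_gain = np.repeat(
        [1.0 if c == EYES_OPEN else profile.alpha_reactivity for c in block_codes],
        n_block,
    )

    noise, rhythms = _ongoing_signals(
        rng, profile, n_total, fs, spec.oscillation_mode, profile.noise_scale
    )
    osc_static = rhythms["theta"] + rhythms["beta"]
    alpha = rhythms["alpha"] * alpha_gain

    data = np.empty((len(CHANNELS), n_total))
    for ci, ch in enumerate(CHANNELS):
        if ch in MASTOIDS:
            np.multiply(noise[ci], 0.5, out=data[ci])
        else:
            np.add(noise[ci], osc_static, out=data[ci])
            data[ci] += alpha

    events = [
        Event(b * n_block, n_block, block_codes[b]) for b in range(n_blocks)
    ]
    return Recording(data, fs, list(CHANNELS), events)


# ---------------------------------------------------------------------------
# Flanker simulation
# ---------------------------------------------------------------------------

def _template(shape: tuple, topography: dict[str, float], fs: float) -> np.ndarray:
    """Per-channel Gaussian bump, scaled so its measurement-window mean is 1
    at the topography's peak electrode."""
    peak_ms, sd_ms, (w0, w1) = shape
    t_ms = np.arange(int(round(fs))) * 1000.0 / fs  # one second post-stimulus
    g = np.exp(-0.5 * ((t_ms - peak_ms) / sd_ms) ** 2)
    g /= g[(t_ms >= w0) & (t_ms <= w1)].mean()
    weights = np.array([topography.get(ch, 0.0) for ch in CHANNELS])
    return weights[:, None] * g[None, :]


@lru_cache(maxsize=4)
def _erp_injection(fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Templates plus the inverse cross-talk matrix for calibrated injection.

    The N2 and P3 bumps bleed slightly into each other's measurement
    windows, so injecting nominal amplitudes directly would bias the
    measured window means.  Solving the 2x2 mixing system
    ``measured = M @ injected`` and injecting ``M^-1 @ target`` makes the
    noise-free measured window means equal the targets exactly, for any
    amplitude pair.
    """
    n2_tpl = _template(_N2_SHAPE, _N2_TOPOGRAPHY, fs)
    p3_tpl = _template(_P3_SHAPE, _P3_TOPOGRAPHY, fs)
    t_ms = np.arange(n2_tpl.shape[1]) * 1000.0 / fs
    n2_win = (t_ms >= _N2_SHAPE[2][0]) & (t_ms <= _N2_SHAPE[2][1])
    p3_win = (t_ms >= _P3_SHAPE[2][0]) & (t_ms <= _P3_SHAPE[2][1])
    i_fz = CHANNELS.index("Fz")
    i_cpz = CHANNELS.index("CPz")
    mixing = np.array(
        [
            [n2_tpl[i_fz, n2_win].mean(), p3_tpl[i_fz, n2_win].mean()],
            [n2_tpl[i_cpz, p3_win].mean(), p3_tpl[i_cpz, p3_win].mean()],
        ]
    )
    unmix = np.linalg.inv(mixing)
    unmix.setflags(write=False)
    return n2_tpl, p3_tpl, unmix


def simulate_flanker(
    profile: SubjectProfile,
    spec: CohortSpec,
    max_duration_s: float | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """One flanker-task recording plus its behavioral trial table.

    Trials follow fixation (300 ms) → blank (1200–1600 ms) → 200 ms stimulus
    → inter-trial interval (2000–2400 ms); condition order is a random
    permutation with exact 50/50 counts.  Stimulus-locked N2/P3 templates are
    added to the ongoing background; their window-mean amplitudes equal the
    profile's per-condition targets exactly in the noise-free limit.  RTs are
    truncated-normal (> 150 ms); correctness is Bernoulli per condition.
    """
    if spec.n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    fs = spec.sampling_rate
    rng = _subject_rng(spec, profile.subject_index, stage=2)
    n_trials = 2 * spec.n_trials_per_condition
    conditions = np.array(
        ["congruent"] * spec.n_trials_per_condition
        + ["incongruent"] * spec.n_trials_per_condition
    )
    rng.shuffle(conditions)

    blanks = rng.uniform(*_BLANK_S, size=n_trials)
    itis = rng.uniform(*_ITI_S, size=n_trials)
    onsets = np.empty(n_trials, dtype=np.int64)
    t = 1.0  # lead-in, seconds
    for i in range(n_trials):
        stim = t + _FIXATION_S + blanks[i]
        onsets[i] = int(round(stim * fs))
        t = stim + _STIMULUS_S + itis[i]

    needed_s = math.ceil(onsets[-1] / fs + 1.5)
    if max_duration_s is not None and needed_s > max_duration_s:
        raise ValueError(
            f"trial schedule needs {needed_s}s but the recording is capped at "
            f"{max_duration_s}s"
        )
    # round up to a 32 s grid so spectral-shaping tables are shared across
    # subjects; the extra silent tail carries no trials
    duration_s = needed_s if max_duration_s is not None else 32 * math.ceil(needed_s / 32)
    n_total = int(duration_s * fs)

    # ongoing background: 1/f noise per channel + coherent eyes-open rhythms
    data = np.empty((len(CHANNELS), n_total))
    if profile.trial_noise_sd > 0:
        noise, rhythms = _ongoing_signals(
            rng, profile, n_total, fs, spec.oscillation_mode, profile.trial_noise_sd
        )
        osc = rhythms["theta"] + rhythms["alpha"] + rhythms["beta"]
        for ci, ch in enumerate(CHANNELS):
            if ch in MASTOIDS:
                np.multiply(noise[ci], 0.5, out=data[ci])
            else:
                np.add(noise[ci], osc, out=data[ci])
    else:
        data[:] = 0.0

    n2_tpl, p3_tpl, unmix = _erp_injection(fs)
    tpl_len = n2_tpl.shape[1]
    inject = {
        cond: unmix
        @ np.array([profile.erp_amp[f"N2_{cond}"], profile.erp_amp[f"P3_{cond}"]])
        for cond in ("congruent", "incongruent")
    }
    for i, onset in enumerate(onsets):
        a_n2, a_p3 = inject[conditions[i]]
        stop = min(onset + tpl_len, n_total)
        seg = slice(onset, stop)
        data[:, seg] += a_n2 * n2_tpl[:, : stop - onset]
        data[:, seg] += a_p3 * p3_tpl[:, : stop - onset]

    rt_mean = {
        "congruent": profile.rt_congruent_mean,
        "incongruent": profile.rt_congruent_mean + profile.rt_interference_true,
    }
    rts = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    for cond in ("congruent", "incongruent"):
        sel = conditions == cond
        a = (_RT_FLOOR - rt_mean[cond]) / profile.rt_trial_sd
        rts[sel] = st.truncnorm.rvs(
            a, np.inf, loc=rt_mean[cond], scale=profile.rt_trial_sd,
            size=int(sel.sum()), random_state=rng,
        )
        correct[sel] = rng.random(int(sel.sum())) < profile.accuracy_prob[cond]

    trials = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "condition": conditions,
            "onset_sample": onsets,
            "rt_ms": rts,
            "correct": correct,
        }
    )
    validate_trial_table(trials)

    stim_samples = int(round(_STIMULUS_S * fs))
    events = [
        Event(int(onsets[i]), stim_samples, str(conditions[i])) for i in range(n_trials)
    ]
    return Recording(data, fs, list(CHANNELS), events), trials


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the structural invariants of a trial table."""
    required = {"trial_index", "condition", "onset_sample", "rt_ms", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    onsets = trials["onset_sample"].to_numpy()
    if onsets.size > 1 and not (np.diff(onsets) > 0).all():
        raise ValueError("trial onsets must be strictly increasing")
    bad = set(trials["condition"]) - {"congruent", "incongruent"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
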
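"""End-to-end orchestration: simulate → preprocess → spectral → ERP →
behavior → stats, from one config mapping.

A run directory contains per-subject EDF pairs (resting and flanker, each
with an events sidecar), the behavioral tables, the per-subject metric
tables (``spectral_metrics.csv``, ``erpbehav_metrics.csv``), the report
tables, a log, and a reproducibility manifest (config hash, seed, package
version).  Every stage checks for its own outputs first, so deleting a
downstream product and re-running recomputes only what is missing; with a
fixed config the numeric outputs are bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import score_acs, summarize_behavior
from .eegio import Recording, bandpass, read_edf, reject_epochs, rereference_mastoids, write_edf
from .erp import ComponentWindow, epoch_flanker, erp_metrics
from .spectral import BandDefinition, segment_spontaneous, spectral_metrics
from .stats import build_report, paired_t
from .synthcohort import (
    DEFAULT_TARGET_CORRELATIONS,
    LATENT_VARS,
    CohortSpec,
    SubjectProfile,
    make_cohort,
    profiles_to_frame,
    simulate_flanker,
    simulate_resting,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "analyze_resting",
    "analyze_flanker",
    "resting_cohort_metrics",
    "flanker_cohort_metrics",
    "acs_item_responses",
    "DEFAULT_REVERSE_ITEMS",
]

logger = logging.getLogger("attnmark")

#: generator's own ACS keying; scoring with the same set round-trips exactly
DEFAULT_REVERSE_ITEMS = frozenset({1, 5, 9, 13, 17})


class ConfigError(ValueError):
    """Raised when a pipeline config fails validation; carries all errors."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline parameters."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    low_hz: float = 0.5
    high_hz: float = 30.0
    mastoids: tuple[str, str] = ("M1", "M2")
    reject_peak_to_peak_uv: float = 200.0
    n_fft: int = 1024
    epoch_len_ms: float = 1000.0
    bands: dict[str, BandDefinition] = field(
        default_factory=lambda: {
            "theta": BandDefinition("theta", 4.0, 8.0),
            "alpha": BandDefinition("alpha", 8.0, 13.0),
            "beta": BandDefinition("beta", 13.0, 30.0),
        }
    )
    erp_start_ms: float = -200.0
    erp_stop_ms: float = 1000.0
    n2_window: ComponentWindow = field(
        default_factory=lambda: ComponentWindow("N2", "Fz", 230.0, 380.0)
    )
    p3_window: ComponentWindow = field(
        default_factory=lambda: ComponentWindow("P3", "CPz", 400.0, 600.0)
    )
    alpha_level: float = 0.05
    correction: str | None = None
    reverse_items: frozenset[int] = DEFAULT_REVERSE_ITEMS
    failure_tolerance: float = 0.2
    out_dir: Path = Path("attnmark_run")

    def to_dict(self) -> dict:
        """JSON-serializable view used for the manifest hash."""
        return {
            "cohort": {
                "n_subjects": self.cohort.n_subjects,
                "seed": self.cohort.seed,
                "duration_resting_s": self.cohort.duration_resting_s,
                "block_len_s": self.cohort.block_len_s,
                "n_trials_per_condition": self.cohort.n_trials_per_condition,
                "sampling_rate": self.cohort.sampling_rate,
                "oscillation_mode": self.cohort.oscillation_mode,
                "target_correlations": {
                    f"{a},{b}": rho
                    for (a, b), rho in sorted(self.cohort.target_correlations.items())
                },
            },
            "preprocess": {
                "low_hz": self.low_hz,
                "high_hz": self.high_hz,
                "mastoids": list(self.mastoids),
                "reject_peak_to_peak_uv": self.reject_peak_to_peak_uv,
            },
            "spectral": {
                "n_fft": self.n_fft,
                "epoch_len_ms": self.epoch_len_ms,
                "bands": {k: [b.low_hz, b.high_hz] for k, b in self.bands.items()},
            },
            "erp": {
                "start_ms": self.erp_start_ms,
                "stop_ms": self.erp_stop_ms,
                "n2": [self.n2_window.electrode, self.n2_window.start_ms, self.n2_window.end_ms],
                "p3": [self.p3_window.electrode, self.p3_window.start_ms, self.p3_window.end_ms],
            },
            "stats": {"alpha_level": self.alpha_level, "correction": self.correction},
            "behavior": {"reverse_items": sorted(self.reverse_items)},
            "failure_tolerance": self.failure_tolerance,
        }


def _parse_correlations(raw: dict, errors: list[str]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for key, rho in raw.items():
        parts = [p.strip() for p in str(key).split(",")]
        if len(parts) != 2:
            errors.append(f"correlation key {key!r} must be 'var_a,var_b'")
            continue
        a, b = parts
        for name in (a, b):
            if name not in LATENT_VARS:
                errors.append(f"unknown latent variable {name!r} in correlation key {key!r}")
        out[(a, b)] = float(rho)
    return out


def validate_config(raw: dict | None, out_dir: str | Path | None = None,
                    seed: int | None = None) -> PipelineConfig:
    """Normalize a raw (possibly empty) config mapping.

    Every parameter defaults to the standard analysis recipe (0.5–30 Hz
    band-pass, mastoid reference, 200 μV rejection, 1000 ms epochs on a
    1024-point grid, theta/alpha/beta = 4–8/8–13/13–30 Hz, ERP window
    −200–1000 ms with N2 at Fz 230–380 ms and P3 at CPz 400–600 ms,
    α = 0.05).  All violations are collected and raised together as a
    :class:`ConfigError`.
    """
    raw = dict(raw or {})
    errors: list[str] = []

    cohort_raw = dict(raw.get("cohort") or {})
    corr_raw = cohort_raw.pop("target_correlations", None)
    if corr_raw is None:
        corrs = dict(DEFAULT_TARGET_CORRELATIONS)
    else:
        corrs = _parse_correlations(dict(corr_raw), errors)
    cohort_kwargs = {
        k: cohort_raw[k]
        for k in (
            "n_subjects",
            "seed",
            "duration_resting_s",
            "block_len_s",
            "n_trials_per_condition",
            "sampling_rate",
            "oscillation_mode",
        )
        if k in cohort_raw
    }
    if seed is not None:
        cohort_kwargs["seed"] = int(seed)
    cohort = None
    if not errors:
        try:
            cohort = CohortSpec(target_correlations=corrs, **cohort_kwargs)
        except ValueError as exc:
            errors.append(f"cohort: {exc}")

    pre = dict(raw.get("preprocess") or {})
    low = float(pre.get("low_hz", 0.5))
    high = float(pre.get("high_hz", 30.0))
    if not 0 < low < high:
        errors.append(f"preprocess: need 0 < low_hz ({low}) < high_hz ({high})")
    reject = float(pre.get("reject_peak_to_peak_uv", 200.0))
    if reject <= 0:
        errors.append("preprocess: rejection threshold must be positive")
    mastoids = tuple(pre.get("mastoids", ("M1", "M2")))
    if len(mastoids) != 2:
        errors.append(f"preprocess: need exactly two mastoid labels, got {mastoids}")

    spectral_raw = dict(raw.get("spectral") or {})
    n_fft = int(spectral_raw.get("n_fft", 1024))
    epoch_len_ms = float(spectral_raw.get("epoch_len_ms", 1000.0))
    bands_raw = spectral_raw.get(
        "bands", {"theta": [4.0, 8.0], "alpha": [8.0, 13.0], "beta": [13.0, 30.0]}
    )
    bands: dict[str, BandDefinition] = {}
    for name, edges in dict(bands_raw).items():
        lo, hi = float(edges[0]), float(edges[1])
        if not lo < hi:
            errors.append(f"spectral: band {name} edges out of order ({lo}, {hi})")
        else:
            bands[name] = BandDefinition(name, lo, hi)
    for required in ("theta", "alpha", "beta"):
        if required not in bands_raw:
            errors.append(f"spectral: band {required!r} must be defined")

    erp_raw = dict(raw.get("erp") or {})
    start_ms = float(erp_raw.get("start_ms", -200.0))
    stop_ms = float(erp_raw.get("stop_ms", 1000.0))
    if not start_ms < 0 <= stop_ms:
        errors.append(f"erp: window [{start_ms}, {stop_ms}) must straddle stimulus onset")

    def window(name: str, default: tuple[str, float, float]) -> ComponentWindow | None:
        w = erp_raw.get(name.lower())
        el, s, e = default
        if w is not None:
            el = w.get("electrode", el)
            s = float(w.get("start_ms", s))
            e = float(w.get("end_ms", e))
        if not s < e:
            errors.append(f"erp: {name} window start {s} >= end {e}")
            return None
        if not (start_ms <= s and e < stop_ms):
            errors.append(f"erp: {name} window [{s}, {e}] outside epoch [{start_ms}, {stop_ms})")
            return None
        return ComponentWindow(name, el, s, e)

    n2 = window("N2", ("Fz", 230.0, 380.0))
    p3 = window("P3", ("CPz", 400.0, 600.0))

    stats_raw = dict(raw.get("stats") or {})
    alpha_level = float(stats_raw.get("alpha_level", 0.05))
    if not 0 < alpha_level < 1:
        errors.append(f"stats: alpha_level {alpha_level} outside (0, 1)")
    correction = stats_raw.get("correction")
    if correction not in (None, "bonferroni", "fdr_bh"):
        errors.append(f"stats: unknown correction {correction!r}")

    tol = float(raw.get("failure_tolerance", 0.2))
    if not 0 <= tol < 1:
        errors.append(f"failure_tolerance {tol} outside [0, 1)")

    reverse_items = frozenset(
        int(i) for i in raw.get("behavior", {}).get("reverse_items", DEFAULT_REVERSE_ITEMS)
    )

    if errors:
        raise ConfigError(errors)
    assert cohort is not None and n2 is not None and p3 is not None
    return PipelineConfig(
        cohort=cohort,
        low_hz=low,
        high_hz=high,
        mastoids=mastoids,  # type: ignore[arg-type]
        reject_peak_to_peak_uv=reject,
        n_fft=n_fft,
        epoch_len_ms=epoch_len_ms,
        bands=bands,
        erp_start_ms=start_ms,
        erp_stop_ms=stop_ms,
        n2_window=n2,
        p3_window=p3,
        alpha_level=alpha_level,
        correction=correction,
        reverse_items=reverse_items,
        failure_tolerance=tol,
        out_dir=Path(out_dir) if out_dir is not None else Path(raw.get("out_dir", "attnmark_run")),
    )


# ---------------------------------------------------------------------------
# Per-subject analyses (library surface; file-free)
# ---------------------------------------------------------------------------

def _preprocess(recording: Recording, config: PipelineConfig) -> Recording:
    filtered = bandpass(recording, config.low_hz, config.high_hz)
    return rereference_mastoids(filtered, config.mastoids)


def analyze_resting(recording: Recording, config: PipelineConfig) -> pd.DataFrame:
    """Preprocess a resting recording and return its spectral metric rows."""
    clean = _preprocess(recording, config)
    eyes_open, eyes_closed = segment_spontaneous(clean, config.epoch_len_ms)
    eyes_open, _ = reject_epochs(eyes_open, config.reject_peak_to_peak_uv)
    eyes_closed, _ = reject_epochs(eyes_closed, config.reject_peak_to_peak_uv)
    return spectral_metrics(
        eyes_open, eyes_closed, bands=config.bands, n_fft=config.n_fft
    )


def analyze_flanker(
    recording: Recording, trials: pd.DataFrame, config: PipelineConfig
) -> dict[str, float]:
    """Preprocess a flanker recording and return ERP + behavioral metrics."""
    clean = _preprocess(recording, config)
    epochs, excluded = epoch_flanker(clean, trials, config.erp_start_ms, config.erp_stop_ms)
    if excluded:
        logger.warning("excluded %d out-of-bounds trials", len(excluded))
    epochs, _ = reject_epochs(epochs, config.reject_peak_to_peak_uv)
    metrics = erp_metrics(epochs, config.n2_window, config.p3_window)
    behav = summarize_behavior(trials)
    metrics["rt_congruent"] = behav.loc["congruent", "rt_mean"]
    metrics["rt_incongruent"] = behav.loc["incongruent", "rt_mean"]
    metrics["rt_interference"] = metrics["rt_incongruent"] - metrics["rt_congruent"]
    metrics["acc_congruent"] = behav.loc["congruent", "accuracy"]
    metrics["acc_incongruent"] = behav.loc["incongruent", "accuracy"]
    return metrics


def resting_cohort_metrics(config: PipelineConfig) -> pd.DataFrame:
    """Simulate and analyze the resting arm for every subject, in memory.

    One row per subject x eye condition x electrode, carrying the subject's
    ACS total alongside the spectral metrics, ready for correlation.
    """
    frames = []
    for p in make_cohort(config.cohort):
        rec = simulate_resting(p, config.cohort)
        df = analyze_resting(rec, config)
        df.insert(0, "subject_id", p.subject_id)
        df["acs_total"] = p.acs_total
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def flanker_cohort_metrics(config: PipelineConfig) -> pd.DataFrame:
    """Simulate and analyze the flanker arm for every subject, in memory."""
    rows = []
    for p in make_cohort(config.cohort):
        rec, trials = simulate_flanker(p, config.cohort)
        metrics = analyze_flanker(rec, trials, config)
        rows.append({"subject_id": p.subject_id, "acs_total": p.acs_total, **metrics})
    return pd.DataFrame(rows)


def acs_item_responses(
    total: int,
    rng: np.random.Generator,
    reverse_items: frozenset[int] = DEFAULT_REVERSE_ITEMS,
) -> list[int]:
    """Draw a 20-item response pattern whose keyed sum equals ``total``.

    The keyed (direction-corrected) item values are built by distributing
    ``total − 20`` increments at random over items capped at 4; reverse-keyed
    items are then stored as ``5 − value`` so that scoring with the same
    keying recovers ``total`` exactly.
    """
    if not 20 <= total <= 80:
        raise ValueError(f"ACS total {total} outside [20, 80]")
    keyed = np.ones(20, dtype=int)
    budget = total - 20
    while budget > 0:
        open_items = np.nonzero(keyed < 4)[0]
        take = rng.choice(open_items)
        keyed[take] += 1
        budget -= 1
    return [int(5 - k) if i in reverse_items else int(k) for i, k in enumerate(keyed)]


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _simulate_stage(config: PipelineConfig, run_dir: Path) -> list[SubjectProfile]:
    profiles = make_cohort(config.cohort)
    marker = run_dir / "cohort_profiles.csv"
    if marker.exists():
        logger.info("simulate: outputs present, skipping")
        return profiles
    subj_dir = run_dir / "subjects"
    subj_dir.mkdir(parents=True, exist_ok=True)
    acs_rows = []
    for p in profiles:
        resting = simulate_resting(p, config.cohort)
        write_edf(resting, subj_dir / f"{p.subject_id}_resting.edf")
        flanker, trials = simulate_flanker(p, config.cohort)
        write_edf(flanker, subj_dir / f"{p.subject_id}_flanker.edf")
        trials.to_csv(subj_dir / f"{p.subject_id}_trials.csv", index=False)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.cohort.seed, spawn_key=(p.subject_index, 3))
        )
        items = acs_item_responses(p.acs_total, rng, config.reverse_items)
        acs_rows.append({"subject_id": p.subject_id, **{f"item_{i + 1:02d}": v for i, v in enumerate(items)}})
        logger.info("simulated %s", p.subject_id)
    pd.DataFrame(acs_rows).to_csv(run_dir / "acs_responses.csv", index=False)
    profiles_to_frame(profiles).to_csv(marker, index=False)
    return profiles


def _spectral_stage(config: PipelineConfig, run_dir: Path,
                    profiles: list[SubjectProfile]) -> pd.DataFrame:
    out_path = run_dir / "spectral_metrics.csv"
    if out_path.exists():
        logger.info("spectral: outputs present, skipping")
        return pd.read_csv(out_path)
    frames, failures = [], []
    for p in profiles:
        try:
            rec = read_edf(run_dir / "subjects" / f"{p.subject_id}_resting.edf")
            df = analyze_resting(rec, config)
            df.insert(0, "subject_id", p.subject_id)
            frames.append(df)
        except Exception as exc:  # noqa: BLE001 - per-subject fault isolation
            failures.append(p.subject_id)
            logger.error("spectral failed for %s: %s", p.subject_id, exc)
    _check_failures(failures, len(profiles), config, "spectral")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out_path, index=False)
    return table


def _erp_stage(config: PipelineConfig, run_dir: Path,
               profiles: list[SubjectProfile]) -> pd.DataFrame:
    out_path = run_dir / "erpbehav_metrics.csv"
    if out_path.exists():
        logger.info("erp: outputs present, skipping")
        return pd.read_csv(out_path)
    acs_tbl = pd.read_csv(run_dir / "acs_responses.csv").set_index("subject_id")
    rows, failures = [], []
    for p in profiles:
        try:
            rec = read_edf(run_dir / "subjects" / f"{p.subject_id}_flanker.edf")
            trials = pd.read_csv(run_dir / "subjects" / f"{p.subject_id}_trials.csv")
            metrics = analyze_flanker(rec, trials, config)
            items = [int(v) for v in acs_tbl.loc[p.subject_id]]
            metrics["acs_total"] = score_acs(items, config.reverse_items)
            rows.append({"subject_id": p.subject_id, **metrics})
        except Exception as exc:  # noqa: BLE001
            failures.append(p.subject_id)
            logger.error("erp failed for %s: %s", p.subject_id, exc)
    _check_failures(failures, len(profiles), config, "erp")
    table = pd.DataFrame(rows)
    table.to_csv(out_path, index=False)
    return table


def _check_failures(failures: list[str], n: int, config: PipelineConfig, stage: str) -> None:
    if failures and len(failures) / n > config.failure_tolerance:
        raise RuntimeError(
            f"{stage}: {len(failures)}/{n} subjects failed "
            f"(tolerance {config.failure_tolerance:.0%}): {failures}"
        )


def _stats_stage(config: PipelineConfig, run_dir: Path, spectral_tbl: pd.DataFrame,
                 erpbehav_tbl: pd.DataFrame) -> None:
    report = build_report(spectral_tbl, erpbehav_tbl, correction=config.correction)
    for name, tbl in report.items():
        tbl.to_csv(run_dir / f"report_{name}.csv")
    # condition contrasts (eyes-open vs eyes-closed spectra) as a tidy table
    results = []
    n_subj = erpbehav_tbl["subject_id"].nunique()
    if n_subj < 3:
        logger.warning(
            "only %d subject(s): correlation p-values are degenerate", n_subj
        )
    if n_subj >= 2:
        wide = spectral_tbl.pivot_table(
            index="subject_id", columns=["condition", "electrode"],
            values=["theta_beta_ratio_sqrt", "alpha_power_sqrt"],
        )
        for metric in ("theta_beta_ratio_sqrt", "alpha_power_sqrt"):
            for el in ("Fz", "Cz", "Pz"):
                try:
                    res = paired_t(
                        wide[(metric, "eyes_open", el)].to_numpy(),
                        wide[(metric, "eyes_closed", el)].to_numpy(),
                        label=f"{metric}_{el}_open_vs_closed",
                    )
                    results.append(dataclasses.asdict(res))
                except ValueError as exc:
                    logger.warning("paired t degenerate for %s at %s: %s", metric, el, exc)
    pd.DataFrame(results).to_csv(run_dir / "stats_results.csv", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage into ``config.out_dir`` and return the run directory."""
    run_dir = config.out_dir
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        profiles = _simulate_stage(config, run_dir)
        spectral_tbl = _spectral_stage(config, run_dir, profiles)
        erpbehav_tbl = _erp_stage(config, run_dir, profiles)
        _stats_stage(config, run_dir, spectral_tbl, erpbehav_tbl)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "seed": config.cohort.seed,
            "attnmark_version": __version__,
            "n_subjects": config.cohort.n_subjects,
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run_dir
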
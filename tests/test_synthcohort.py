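"""Cohort generation, latent correlation recovery, and signal simulation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from attnmark.eegio import rereference_mastoids
from attnmark.spectral import (
    DEFAULT_BANDS,
    EYES_CLOSED,
    EYES_OPEN,
    band_power,
    segment_spontaneous,
    welch_psd,
)
from attnmark.synthcohort import (
    CohortSpec,
    CorrelationSpecError,
    make_cohort,
    profiles_to_frame,
    simulate_flanker,
    simulate_resting,
    validate_trial_table,
)


class TestCohortSpec:
    def test_unknown_variable_and_out_of_range_rho_refused(self):
        with pytest.raises(ValueError, match="unknown latent"):
            CohortSpec(target_correlations={("acs_total", "nope"): 0.3})
        with pytest.raises(ValueError, match=r"\(-1, 1\)"):
            CohortSpec(target_correlations={("acs_total", "p3d_true"): 1.0})

    def test_non_psd_matrix_names_offending_pair(self):
        bad = {
            ("acs_total", "theta_beta_ratio_true"): 0.9,
            ("theta_beta_ratio_true", "alpha_power_true"): 0.9,
            ("acs_total", "alpha_power_true"): -0.9,
        }
        with pytest.raises(CorrelationSpecError, match="offending"):
            CohortSpec(target_correlations=bad)


class TestMakeCohort:
    def test_same_seed_bitwise_identical(self):
        spec = CohortSpec(n_subjects=5, seed=42)
        assert make_cohort(spec) == make_cohort(spec)

    def test_growing_the_cohort_preserves_existing_subjects(self):
        small = make_cohort(CohortSpec(n_subjects=4, seed=9))
        large = make_cohort(CohortSpec(n_subjects=8, seed=9))
        assert large[:4] == small

    def test_profiles_respect_bounds(self):
        for p in make_cohort(CohortSpec(n_subjects=200, seed=1)):
            assert 20 <= p.acs_total <= 80
            assert p.alpha_reactivity >= 1.0
            assert all(a >= 0 for a in p.band_amplitude.values())
            assert all(0 < v <= 1 for v in p.accuracy_prob.values())

    def test_independent_spec_yields_near_zero_correlations(self):
        df = profiles_to_frame(make_cohort(CohortSpec(10_000, {}, seed=3)))
        cols = [
            "acs_total",
            "theta_beta_ratio_true",
            "alpha_power_true",
            "rt_interference_true",
            "p3d_true",
        ]
        corr = df[cols].corr().to_numpy() - np.eye(len(cols))
        assert np.abs(corr).max() < 0.03

    def test_target_correlation_recovered_at_large_n(self):
        spec = CohortSpec(10_000, {("acs_total", "theta_beta_ratio_true"): -0.263}, seed=7)
        df = profiles_to_frame(make_cohort(spec))
        r = np.corrcoef(df.acs_total, df.theta_beta_ratio_true)[0, 1]
        assert r == pytest.approx(-0.263, abs=0.02)


class TestSimulateResting:
    def test_determinism_and_block_bookkeeping(self, small_spec, small_profiles):
        a = simulate_resting(small_profiles[0], small_spec)
        b = simulate_resting(small_profiles[0], small_spec)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.events == b.events
        n_blocks = int(small_spec.duration_resting_s / small_spec.block_len_s)
        assert len(a.events) == n_blocks
        codes = [e.code for e in a.events]
        assert codes == [EYES_OPEN, EYES_CLOSED] * (n_blocks // 2)

    def test_pure_tone_variance_is_half_amplitude_squared(self, small_profiles):
        amp = 3.0
        p = dataclasses.replace(
            small_profiles[0],
            band_amplitude={"theta": 0.0, "alpha": amp, "beta": 0.0},
            alpha_reactivity=1.0,
            noise_scale=0.0,
        )
        spec = CohortSpec(n_subjects=1, seed=4, duration_resting_s=120.0,
                          oscillation_mode="sinusoid")
        rec = simulate_resting(p, spec)
        for ch in ("Fz", "Cz", "Pz", "CPz"):
            v = rec.data[rec.channel_index(ch)].var()
            assert v == pytest.approx(amp**2 / 2.0, rel=1e-6)
        for ch in ("M1", "M2"):
            assert rec.data[rec.channel_index(ch)].var() == 0.0

    def test_reactivity_two_quadruples_eyes_closed_alpha_power(self, small_profiles):
        p = dataclasses.replace(
            small_profiles[0],
            band_amplitude={"theta": 0.0, "alpha": 2.0, "beta": 0.0},
            alpha_reactivity=2.0,
            noise_scale=0.0,
        )
        spec = CohortSpec(n_subjects=1, seed=4, duration_resting_s=120.0,
                          oscillation_mode="sinusoid")
        eo, ec = segment_spontaneous(simulate_resting(p, spec))
        alpha = DEFAULT_BANDS["alpha"]
        open_p = band_power(welch_psd(eo), alpha)
        closed_p = band_power(welch_psd(ec), alpha)
        fz = 0
        assert closed_p[fz] == pytest.approx(4.0 * open_p[fz], rel=1e-9)

    def test_default_profile_alpha_reactive_at_all_analysis_electrodes(
        self, small_spec, small_profiles
    ):
        rec = rereference_mastoids(simulate_resting(small_profiles[0], small_spec))
        eo, ec = segment_spontaneous(rec)
        alpha = DEFAULT_BANDS["alpha"]
        open_p = band_power(welch_psd(eo), alpha)
        closed_p = band_power(welch_psd(ec), alpha)
        for ch in ("Fz", "Cz", "Pz"):
            i = rec.channel_index(ch)
            assert closed_p[i] > open_p[i]

    def test_duration_not_multiple_of_block_refused(self, small_profiles):
        spec = CohortSpec(n_subjects=1, seed=4, duration_resting_s=90.0)
        with pytest.raises(ValueError, match="multiple"):
            simulate_resting(small_profiles[0], spec)

    @pytest.mark.parametrize("band", ["theta", "alpha", "beta"])
    def test_narrowband_carrier_in_band_power_matches_target(self, small_profiles, band):
        # one carrier at a time: its in-band power is scaled to exactly A^2/2
        amps = {b: 0.0 for b in ("theta", "alpha", "beta")}
        amps[band] = 3.0
        target = 3.0**2 / 2.0
        p = dataclasses.replace(
            small_profiles[0], band_amplitude=amps, noise_scale=0.0, alpha_reactivity=1.0
        )
        spec = CohortSpec(n_subjects=1, seed=4, duration_resting_s=120.0)
        rec = simulate_resting(p, spec)
        lo, hi = DEFAULT_BANDS[band].low_hz, DEFAULT_BANDS[band].high_hz
        x = rec.data[0]
        freqs = np.fft.rfftfreq(x.size, 1.0 / spec.sampling_rate)
        fine = 2.0 * np.abs(np.fft.rfft(x)) ** 2 / x.size**2
        in_band = fine[(freqs >= lo) & (freqs < hi)].sum()
        assert in_band == pytest.approx(target, rel=1e-9)  # exact by construction
        # the epoch-averaged Welch reading recovers it within estimator scatter
        eo, _ = segment_spontaneous(rec)
        measured = band_power(welch_psd(eo), DEFAULT_BANDS[band])[0]
        assert measured == pytest.approx(target, rel=0.12)


class TestSimulateFlanker:
    def test_trial_table_schedule_and_counts(self, small_spec, small_profiles):
        rec, trials = simulate_flanker(small_profiles[0], small_spec)
        validate_trial_table(trials)
        assert (trials.condition == "congruent").sum() == small_spec.n_trials_per_condition
        assert (trials.condition == "incongruent").sum() == small_spec.n_trials_per_condition
        gaps = np.diff(trials.onset_sample.to_numpy())
        assert gaps.min() >= 3700 and gaps.max() <= 4600  # scheduled timing bounds
        assert (trials.rt_ms > 150.0).all()
        assert len(rec.events) == len(trials)

    def test_determinism(self, small_spec, small_profiles):
        r1, t1 = simulate_flanker(small_profiles[1], small_spec)
        r2, t2 = simulate_flanker(small_profiles[1], small_spec)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert t1.equals(t2)

    def test_perfect_accuracy_leaves_no_incorrect_trials(self, small_spec, small_profiles):
        p = dataclasses.replace(
            small_profiles[0], accuracy_prob={"congruent": 1.0, "incongruent": 1.0}
        )
        _, trials = simulate_flanker(p, small_spec)
        assert trials.correct.all()

    def test_reported_rt_means_reproduce_reported_interference(self, small_profiles):
        p = dataclasses.replace(
            small_profiles[0],
            rt_congruent_mean=466.29,
            rt_interference_true=62.45,
            rt_trial_sd=10.0,
        )
        spec = CohortSpec(n_subjects=1, seed=12)  # default 120 trials per condition
        _, trials = simulate_flanker(p, spec)
        by_cond = trials.groupby("condition")["rt_ms"].mean()
        measured = by_cond["incongruent"] - by_cond["congruent"]
        assert measured == pytest.approx(62.45, abs=2.0)

    def test_capped_duration_refused_when_schedule_overruns(self, small_spec, small_profiles):
        with pytest.raises(ValueError, match="capped"):
            simulate_flanker(small_profiles[0], small_spec, max_duration_s=10.0)
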
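"""Stimulus-locked epoching, baseline correction, averaging and amplitudes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from attnmark.eegio import EpochSet, Recording
from attnmark.erp import (
    N2_WINDOW,
    P3_WINDOW,
    ComponentWindow,
    ErpAverage,
    average_condition,
    baseline_correct,
    difference_scores,
    epoch_flanker,
    erp_metrics,
    mean_amplitude,
    select_correct,
)
from attnmark.synthcohort import CohortSpec, make_cohort, simulate_flanker

LABELS = ["Fz", "Cz", "Pz", "CPz", "M1", "M2"]


def _trials(onsets, conditions=None, correct=None) -> pd.DataFrame:
    n = len(onsets)
    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "condition": conditions if conditions is not None else ["congruent"] * n,
            "onset_sample": onsets,
            "rt_ms": np.full(n, 400.0),
            "correct": correct if correct is not None else [True] * n,
        }
    )


def _task_epochs(data: np.ndarray, conditions, correct=None) -> EpochSet:
    n = data.shape[0]
    return EpochSet(
        data,
        1000.0,
        LABELS[: data.shape[1]],
        time_origin_ms=-200.0,
        conditions=np.asarray(conditions, dtype=object),
        correct=np.asarray(correct if correct is not None else [True] * n),
    )


class TestEpochFlanker:
    def test_in_bounds_trials_all_epoched_with_1200_samples(self, rng):
        rec = Recording(rng.normal(size=(6, 20_000)), 1000.0, LABELS)
        onsets = np.arange(500, 18_000, 1500)
        epochs, excluded = epoch_flanker(rec, _trials(onsets))
        assert epochs.n_epochs == len(onsets)
        assert epochs.data.shape[2] == 1200
        assert excluded == []

    def test_edge_trials_excluded_and_logged(self, rng):
        rec = Recording(rng.normal(size=(6, 5000)), 1000.0, LABELS)
        epochs, excluded = epoch_flanker(rec, _trials([100, 2000, 4500]))
        assert epochs.n_epochs == 1
        assert sorted(e["trial_index"] for e in excluded) == [0, 2]
        assert all("outside recording" in e["reason"] for e in excluded)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        ep = _task_epochs(np.full((1, 2, 1200), 7.0), ["congruent"])
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0)

    def test_zero_mean_baseline_unchanged(self, rng):
        data = rng.normal(size=(3, 2, 1200))
        data -= data[:, :, :200].mean(axis=-1, keepdims=True)
        out = baseline_correct(_task_epochs(data, ["congruent"] * 3))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_per_channel_shift_invariance(self, rng):
        data = rng.normal(size=(4, 3, 1200))
        shifted = data + np.array([5.0, -3.0, 11.0])[None, :, None]
        a = baseline_correct(_task_epochs(data, ["congruent"] * 4))
        b = baseline_correct(_task_epochs(shifted, ["congruent"] * 4))
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)


class TestSelectCorrect:
    def test_all_correct_identical_retention(self, rng):
        ep = _task_epochs(rng.normal(size=(6, 2, 1200)), ["congruent"] * 6)
        out = select_correct(ep)
        assert out.n_epochs == 6
        np.testing.assert_array_equal(out.data, ep.data)

    def test_exact_bookkeeping_with_mixed_flags(self, rng):
        n = 60
        correct = np.ones(n, dtype=bool)
        correct[:6] = False  # 10% incorrect
        ep = _task_epochs(rng.normal(size=(n, 1, 1200)), ["congruent"] * n, correct)
        ep.rejected_flags[10:13] = True
        out = select_correct(ep)
        assert out.n_epochs == n - 6 - 3  # AND of both flag sets

    def test_emptied_condition_is_named(self, rng):
        ep = _task_epochs(
            rng.normal(size=(4, 1, 1200)),
            ["congruent", "congruent", "incongruent", "incongruent"],
            [True, True, False, False],
        )
        with pytest.raises(ValueError, match="incongruent"):
            select_correct(ep)


class TestAveraging:
    def test_identical_epochs_average_to_themselves(self):
        proto = np.linspace(-1, 1, 1200)[None, :]
        data = np.repeat(proto[None, :, :], 5, axis=0)
        avg = average_condition(_task_epochs(data, ["congruent"] * 5), "congruent")
        np.testing.assert_allclose(avg.data, proto)
        assert avg.n_trials_averaged == 5

    def test_single_epoch_average_is_that_epoch(self, rng):
        data = rng.normal(size=(1, 2, 1200))
        avg = average_condition(_task_epochs(data, ["incongruent"]), "incongruent")
        np.testing.assert_array_equal(avg.data, data[0])

    def test_residual_noise_shrinks_as_sqrt_n(self, rng):
        sigma, n = 4.0, 120
        data = rng.normal(0.0, sigma, size=(n, 1, 1200))
        avg = average_condition(_task_epochs(data, ["congruent"] * n), "congruent")
        assert avg.data.std() == pytest.approx(sigma / np.sqrt(n), rel=0.20)

    def test_empty_condition_refused(self, rng):
        ep = _task_epochs(rng.normal(size=(2, 1, 1200)), ["congruent"] * 2)
        with pytest.raises(ValueError, match="incongruent"):
            average_condition(ep, "incongruent")


class TestMeanAmplitude:
    def _avg(self, data: np.ndarray) -> ErpAverage:
        return ErpAverage(
            "congruent", data, -200.0 + np.arange(data.shape[1]),
            LABELS[: data.shape[0]], 1,
        )

    def test_flat_waveform_reads_zero(self):
        assert mean_amplitude(self._avg(np.zeros((6, 1200))), N2_WINDOW) == 0.0

    def test_constant_shift_moves_mean_by_exactly_that(self, rng):
        data = rng.normal(size=(6, 1200))
        base = mean_amplitude(self._avg(data), P3_WINDOW)
        shifted = data.copy()
        shifted[LABELS.index("CPz")] += 1.0
        assert mean_amplitude(self._avg(shifted), P3_WINDOW) == pytest.approx(base + 1.0)

    def test_window_endpoints_inclusive(self):
        data = np.zeros((6, 1200))
        # only the endpoint samples (230 ms and 380 ms) are nonzero
        data[0, 430] = 151.0
        data[0, 580] = 151.0
        assert mean_amplitude(self._avg(data), N2_WINDOW) == pytest.approx(2.0)

    def test_window_outside_epoch_refused(self):
        with pytest.raises(ValueError, match="outside"):
            mean_amplitude(
                self._avg(np.zeros((6, 1200))), ComponentWindow("late", "Fz", 900.0, 1100.0)
            )


class TestDifferenceScores:
    def test_reported_amplitudes_give_reported_differences(self):
        n2d, p3d, rt = difference_scores(
            {"congruent": -1.54, "incongruent": -2.59},
            {"congruent": 6.23, "incongruent": 7.30},
            {"congruent": 466.29, "incongruent": 528.74},
        )
        assert n2d == pytest.approx(-1.05)
        assert p3d == pytest.approx(1.07)
        assert rt == pytest.approx(62.45)

    def test_equal_inputs_give_zero(self):
        z = {"congruent": 3.3, "incongruent": 3.3}
        assert difference_scores(z, z, z) == (0.0, 0.0, 0.0)

    def test_missing_condition_refused(self):
        with pytest.raises(ValueError, match="missing"):
            difference_scores({"congruent": 1.0}, {}, {})


@pytest.fixture(scope="module")
def quiet_profile():
    spec = CohortSpec(n_subjects=1, seed=21, n_trials_per_condition=12)
    p = make_cohort(spec)[0]
    return spec, dataclasses.replace(
        p,
        trial_noise_sd=0.0,
        accuracy_prob={"congruent": 1.0, "incongruent": 1.0},
    )


class TestEndToEnd:

    def test_no_noise_template_recovery_to_microvolt_precision(self, quiet_profile):
        spec, base = quiet_profile
        p = dataclasses.replace(
            base,
            erp_amp={
                "N2_congruent": -2.59,
                "N2_incongruent": -4.0,
                "P3_congruent": 6.23,
                "P3_incongruent": 7.30,
            },
        )
        rec, trials = simulate_flanker(p, spec)
        metrics = erp_metrics(epoch_flanker(rec, trials)[0])
        assert abs(metrics["n2_congruent"] - (-2.59)) < 1e-6
        assert abs(metrics["n2d"] - (-1.41)) < 1e-6
        assert abs(metrics["p3d"] - 1.07) < 1e-6

    def test_p3d_strictly_monotone_in_injected_amplitude(self, quiet_profile):
        spec, base = quiet_profile
        measured = []
        for p3_inc in (6.5, 7.5, 8.5):
            p = dataclasses.replace(
                base,
                erp_amp={**base.erp_amp, "P3_incongruent": p3_inc},
            )
            rec, trials = simulate_flanker(p, spec)
            measured.append(erp_metrics(epoch_flanker(rec, trials)[0])["p3d"])
        assert measured[0] < measured[1] < measured[2]

    def test_recording_offset_invariance(self, quiet_profile):
        spec, p = quiet_profile
        rec, trials = simulate_flanker(p, spec)
        m0 = erp_metrics(epoch_flanker(rec, trials)[0])
        shifted = Recording(
            rec.data + np.array([3.0, -8.0, 2.0, 5.0, 0.5, -0.5])[:, None],
            rec.sampling_rate,
            rec.channel_labels,
            rec.events,
        )
        m1 = erp_metrics(epoch_flanker(shifted, trials)[0])
        for key in ("n2_congruent", "n2_incongruent", "p3_congruent", "p3_incongruent"):
            assert m1[key] == pytest.approx(m0[key], abs=1e-9)
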
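"""Sleep-scoring, transition and sub-state onset tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from somnophot.scoring import (
    Hypnogram,
    ScoringThresholds,
    classify_epochs,
    detect_substate_onsets,
    detect_transitions,
    emg_metric_1s,
    epoch_features,
    refine_to_seconds,
    score_recording,
)
from tests.conftest import majority_epoch_labels


class TestEpochFeatures:
    def test_pure_delta_sine_dominates_total(self):
        rate = 200.0
        t = np.arange(0, 40, 1 / rate)
        eeg = np.sin(2 * np.pi * 2.0 * t)
        feats = epoch_features(eeg, np.zeros_like(eeg), rate)
        assert np.all(feats["delta_power"] / feats["total_power"] > 0.9)

    def test_zero_emg_gives_zero_rms(self):
        rate = 200.0
        eeg = np.random.default_rng(0).normal(size=int(rate * 20))
        feats = epoch_features(eeg, np.zeros_like(eeg), rate)
        assert np.allclose(feats["emg_rms"], 0.0)

    def test_white_noise_delta_fraction_matches_bandwidth_ratio(self):
        rate = 200.0
        eeg = np.random.default_rng(1).normal(size=int(rate * 600))
        feats = epoch_features(eeg, eeg, rate)
        frac = (feats["delta_power"] / feats["total_power"]).mean()
        expected = 3.5 / (rate / 2 - 0.5)
        assert frac == pytest.approx(expected, rel=0.2)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            epoch_features(np.zeros(1000), np.zeros(1000), 200.0, epoch_len=2.0)


class TestClassify:
    def make_features(self, emg, delta, theta):
        n = len(emg)
        return pd.DataFrame(
            {
                "epoch": np.arange(n),
                "t_start": 4.0 * np.arange(n),
                "delta_power": delta,
                "theta_power": theta,
                "total_power": np.asarray(delta) + np.asarray(theta),
                "emg_rms": emg,
            }
        )

    def test_high_emg_is_wake_regardless_of_spectrum(self):
        feats = self.make_features([50.0], [100.0], [1.0])
        hyp = classify_epochs(feats, ScoringThresholds(emg_rms=20.0))
        assert hyp.epoch_labels[0] == "wake"

    def test_low_emg_delta_dominant_is_nrem(self):
        feats = self.make_features([5.0], [10.0], [1.0])
        hyp = classify_epochs(feats, ScoringThresholds(emg_rms=20.0))
        assert hyp.epoch_labels[0] == "nrem"

    def test_low_emg_theta_dominant_is_rem(self):
        feats = self.make_features([5.0], [1.0], [10.0])
        hyp = classify_epochs(feats, ScoringThresholds(emg_rms=20.0))
        assert hyp.epoch_labels[0] == "rem"

    def test_nonfinite_features_flagged_and_inherited(self):
        feats = self.make_features([5.0, np.nan, 5.0], [10.0, 1.0, 10.0], [1.0, 1.0, 1.0])
        hyp = classify_epochs(feats, ScoringThresholds(emg_rms=20.0))
        assert hyp.epoch_labels[1] == "unsc"
        sec = refine_to_seconds(hyp)
        assert np.all(sec[4:8] == "nrem")  # inherits previous epoch

    def test_isolated_rem_in_wake_smoothed_away(self):
        feats = self.make_features([50, 5, 50], [1, 1, 1], [10, 10, 10])
        hyp = classify_epochs(feats, ScoringThresholds(emg_rms=20.0, smooth=True))
        assert list(hyp.epoch_labels) == ["wake", "wake", "wake"]

    def test_full_recording_accuracy_vs_ground_truth(self, two_hour_recording):
        cfg, rec, truth = two_hour_recording
        hyp = score_recording(rec)
        true_ep = majority_epoch_labels(truth.second_labels, 4, hyp.n_epochs)
        acc = np.mean(hyp.epoch_labels == true_ep)
        assert acc >= 0.95


class TestRefine:
    def test_epochs_expand_to_seconds(self):
        hyp = Hypnogram(epoch_labels=np.array(["nrem", "wake"]), epoch_len=4.0)
        sec = refine_to_seconds(hyp)
        assert list(sec) == ["nrem"] * 4 + ["wake"] * 4

    def test_boundary_refinement_moves_wake_onset_earlier(self):
        hyp = Hypnogram(epoch_labels=np.array(["nrem", "wake"]), epoch_len=4.0)
        emg = np.array([1.0, 1.0, 9.0, 9.0, 9.0, 9.0, 9.0, 9.0])  # crosses at s=2
        sec = refine_to_seconds(hyp, emg_metric=emg, emg_threshold=5.0,
                                boundary_refinement=True)
        assert list(sec) == ["nrem", "nrem", "wake", "wake"] + ["wake"] * 4

    def test_single_state_unchanged_by_refinement(self):
        hyp = Hypnogram(epoch_labels=np.array(["rem"] * 5), epoch_len=4.0)
        emg = np.full(20, 9.0)
        sec = refine_to_seconds(hyp, emg, 5.0, boundary_refinement=True)
        assert set(sec) == {"rem"}

    def test_refinement_preserves_state_multiset(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["wake", "nrem"], size=30)
        hyp = Hypnogram(epoch_labels=labels, epoch_len=4.0)
        emg = rng.uniform(0, 10, size=120)
        sec = refine_to_seconds(hyp, emg, 5.0, boundary_refinement=True)
        assert set(sec) == set(labels)


def brute_force_transitions(labels, frm, to, min_after):
    out = []
    n = len(labels)
    for t in range(1, n):
        if labels[t - 1] == frm and labels[t] == to:
            run = 0
            while t + run < n and labels[t + run] == to:
                run += 1
            if run >= min_after:
                out.append((t, run))
    return out


class TestTransitions:
    def test_simple_transition_with_bout_duration(self):
        labels = np.array(["nrem"] * 60 + ["wake"] * 40)
        trs = detect_transitions(labels, "nrem", "wake")
        assert len(trs) == 1
        assert trs[0].time == 60.0
        assert trs[0].bout_duration_after == 40.0

    def test_short_wake_bout_excluded_by_min_bout(self):
        labels = np.array(["nrem"] * 60 + ["wake"] * 20 + ["nrem"] * 20)
        assert detect_transitions(labels, "nrem", "wake", min_bout_after=30) == []

    def test_stim_within_window_flags_evoked(self):
        labels = np.array(["nrem"] * 58 + ["wake"] * 42)
        trs = detect_transitions(labels, "nrem", "wake", stim_onsets=[55.0])
        assert trs[0].evoked
        trs2 = detect_transitions(labels, "nrem", "wake", stim_onsets=[10.0])
        assert not trs2[0].evoked

    @given(hst.lists(hst.sampled_from(["wake", "nrem", "rem"]), min_size=2, max_size=200),
           hst.integers(min_value=0, max_value=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_scan(self, labels, min_after):
        labels = np.array(labels)
        got = [(t.time, t.bout_duration_after)
               for t in detect_transitions(labels, "nrem", "wake", min_bout_after=min_after)]
        assert got == [(float(a), float(b))
                       for a, b in brute_force_transitions(labels, "nrem", "wake", min_after)]


class TestSubstateOnsets:
    def test_threshold_arithmetic(self):
        rng = np.random.default_rng(0)
        m = rng.normal(1.0, 0.1, size=600)
        labels = np.array(["nrem"] * 600)
        # force supra-threshold run to check the recorded threshold value
        m[300] = 10.0
        onsets = detect_substate_onsets(m, labels, "nrem", k=10.0)
        vals = m
        expected = vals.mean() + 10.0 * vals.std()
        assert onsets[0].threshold_used == pytest.approx(expected)

    def test_constant_emg_single_burst_detected(self):
        m = np.full(300, 1.0)
        m[150:152] = 10.0
        labels = np.array(["nrem"] * 300)
        onsets = detect_substate_onsets(m, labels, "nrem", k=10.0)
        assert len(onsets) == 1
        assert abs(onsets[0].time - 150.0) <= 1.0
        assert onsets[0].kind == "micro_awakening"

    def test_no_suprathreshold_samples_empty(self):
        m = np.full(120, 1.0)
        labels = np.array(["wake"] * 120)
        assert detect_substate_onsets(m, labels, "wake", k=10.0) == []

    def test_refractory_gap_merges_nearby_runs(self):
        m = np.full(3000, 1.0)
        m[100] = 20.0
        m[104] = 20.0  # within the 8-s refractory gap
        m[200] = 20.0
        labels = np.array(["wake"] * 3000)
        onsets = detect_substate_onsets(m, labels, "wake", k=10.0)
        assert [o.time for o in onsets] == [100.0, 200.0]
        assert all(o.kind == "active_awake_onset" for o in onsets)

    def test_insufficient_parent_state_rejected(self):
        m = np.full(30, 1.0)
        labels = np.array(["nrem"] * 30)
        with pytest.raises(ValueError, match="60 s"):
            detect_substate_onsets(m, labels, "nrem")

    def test_k_sd_alternative_rule(self):
        m = np.full(100, 5.0)
        m[:10] = np.linspace(4, 6, 10)  # small spread
        labels = np.array(["nrem"] * 100)
        m2 = m.copy()
        m2[50] = 50.0
        onsets = detect_substate_onsets(m2, labels, "nrem", k=10.0, threshold_rule="k_sd")
        sd = m2.std()
        assert onsets[0].threshold_used == pytest.approx(10.0 * sd)

    def test_injected_bursts_recovered_on_synthetic_recording(self, burst_recording):
        cfg, rec, truth = burst_recording
        metric = emg_metric_1s(rec.channels["EMG"].samples, rec.channels["EMG"].rate)
        for state in ("nrem", "wake"):
            expected = [t for (t, _, _) in cfg.emg_bursts
                        if truth.second_labels[int(t)] == state]
            onsets = detect_substate_onsets(metric, truth.second_labels, state, k=10.0)
            got = [o.time for o in onsets]
            assert len(got) == len(expected)
            for t in expected:
                assert min(abs(g - t) for g in got) <= 4.0

    def test_zero_false_onsets_on_burst_free_recording(self, two_hour_recording):
        cfg, rec, truth = two_hour_recording
        metric = emg_metric_1s(rec.channels["EMG"].samples, rec.channels["EMG"].rate)
        for state in ("nrem", "wake"):
            assert detect_substate_onsets(metric, truth.second_labels, state, k=10.0) == []
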
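"""Synthetic-data generator: cohorts, trial tables, slots-model behaviour, EEG."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import cdakit as ck
from cdakit.simulate import DEFAULT_GROUP_PARAMS, GroupParams, _balanced_bools


class TestCohort:
    def test_default_cohort_sizes_and_inclusion_ranges(self):
        cohort = ck.make_cohort(18, seed=1)
        assert len(cohort.participants) == 36
        dep = cohort.group("depressed")
        con = cohort.group("control")
        assert len(dep) == len(con) == 18
        assert all(p.bdi >= 14 for p in dep)
        assert all(p.bdi <= 9 for p in con)
        assert len({p.id for p in cohort.participants}) == 36

    def test_degenerate_zero_sd_returns_mean_exactly(self):
        params = {
            "depressed": dataclasses.replace(
                DEFAULT_GROUP_PARAMS["depressed"], bdi_sd=0.0),
            "control": DEFAULT_GROUP_PARAMS["control"],
        }
        cohort = ck.make_cohort(1, params, seed=0)
        (dep,) = cohort.group("depressed")
        assert dep.bdi == 26.83

    def test_determinism(self):
        a = ck.make_cohort(5, seed=42)
        b = ck.make_cohort(5, seed=42)
        assert a.to_frame().equals(b.to_frame())

    def test_overlapping_inclusion_ranges_rejected(self):
        params = {
            "depressed": dataclasses.replace(
                DEFAULT_GROUP_PARAMS["depressed"], bdi_range=(5.0, 63.0), bdi_mean=10.0),
            "control": DEFAULT_GROUP_PARAMS["control"],
        }
        with pytest.raises(ValueError, match="overlap"):
            ck.make_cohort(3, params, seed=0)


class TestTrialTable:
    def test_default_design_counts(self):
        t = ck.simulate_trial_table(ck.TaskConfig(), seed=0)
        assert len(t) == 600
        assert t.groupby("condition").size().eq(200).all()
        assert t["change_present"].sum() == 300
        assert (t["cue_side"] == "left").sum() == 300
        assert t["block"].value_counts().eq(50).all()

    def test_two_trials_per_condition_counterbalance(self):
        t = ck.simulate_trial_table(
            ck.TaskConfig(n_trials_per_condition=2, n_blocks=1), seed=0)
        assert len(t) == 6
        per = t.groupby("condition")["change_present"].sum()
        assert per.eq(1).all()

    def test_odd_count_raises_naming_constraint(self):
        with pytest.raises(ValueError, match="counterbalance"):
            ck.simulate_trial_table(
                ck.TaskConfig(n_trials_per_condition=3, n_blocks=1), seed=0)

    @settings(max_examples=20, deadline=None)
    @given(n=hst.integers(1, 40).map(lambda k: 2 * k), seed=hst.integers(0, 2 ** 20))
    def test_counterbalancing_property(self, n, seed):
        """Per condition, change and cue-side margins are off by at most one."""
        t = ck.simulate_trial_table(
            ck.TaskConfig(n_trials_per_condition=n, n_blocks=1), seed=seed)
        for _, sub in t.groupby("condition"):
            assert abs(int(sub["change_present"].sum()) * 2 - n) <= 1
            assert abs((sub["cue_side"] == "left").sum() * 2 - n) <= 1

    def test_determinism(self):
        a = ck.simulate_trial_table(seed=9)
        b = ck.simulate_trial_table(seed=9)
        assert a.equals(b)


class TestSlotsModel:
    def test_ceiling_capacity_is_perfect(self):
        t = ck.simulate_vwm_task(6.0, 200, 6, lapse=0.0, seed=0)
        from cdakit.behavior import cowan_k, hit_false_alarm

        h, f = hit_false_alarm(t)
        assert (h, f) == (1.0, 0.0)
        assert cowan_k(h, f, 6) == 6.0

    def test_analytic_rates_at_half_capacity(self):
        """true_k=3, N=6, g=0.5 gives H=0.75, F=0.25 in expectation."""
        t = ck.simulate_vwm_task(3.0, 200_000, 6, guess_rate=0.5, seed=1)
        from cdakit.behavior import hit_false_alarm

        h, f = hit_false_alarm(t)
        assert h == pytest.approx(0.75, abs=0.005)
        assert f == pytest.approx(0.25, abs=0.005)

    @pytest.mark.parametrize("true_k", [0.0, 2.5, 6.0])
    def test_k_estimator_unbiased(self, true_k):
        """Monte-Carlo check of the slots identity E[K-hat] = true_k."""
        from cdakit.behavior import cowan_k, hit_false_alarm

        reps = 400
        ks = np.empty(reps)
        for r in range(reps):
            t = ck.simulate_vwm_task(true_k, 100, 6, seed=10_000 + r)
            ks[r] = cowan_k(*hit_false_alarm(t), 6)
        se = ks.std(ddof=1) / np.sqrt(reps)
        assert abs(ks.mean() - true_k) <= max(3 * se, 1e-12)

    def test_lapse_pulls_toward_chance(self):
        t = ck.simulate_vwm_task(6.0, 50_000, 6, lapse=1.0, seed=2)
        assert t["correct"].mean() == pytest.approx(0.5, abs=0.01)

    def test_determinism(self):
        a = ck.simulate_vwm_task(2.0, 100, seed=3)
        b = ck.simulate_vwm_task(2.0, 100, seed=3)
        assert a.equals(b)


class TestEpochSimulation:
    def test_noise_free_injection_exact(self, noisefree_epochs):
        """With zero noise the contra-ipsi window mean equals ground truth exactly."""
        epochs, table = noisefree_epochs
        for cond in ck.CONDITIONS:
            contra, ipsi = ck.contra_ipsi_waves(epochs, table, ck.Montage(), cond)
            wm = ck.window_mean(contra - ipsi, epochs.times, (500, 1000))
            assert wm == pytest.approx(-1.0, abs=1e-12)

    def test_null_ground_truth_gives_zero_difference(self, tiny_task):
        rec = ck.ParticipantRecord("p0", "control", 0.0, 0.0, 3.0,
                                   {c: 0.0 for c in ck.CONDITIONS})
        table = ck.simulate_trial_table(tiny_task, seed=4)
        epochs = ck.simulate_epochs(table, rec, ck.EEGSimConfig(noise_sd=0.0))
        contra, ipsi = ck.contra_ipsi_waves(epochs, table, ck.Montage(), "non_dis")
        assert np.allclose(contra - ipsi, 0.0)

    def test_component_waveform_window_mean_is_one(self):
        times = np.arange(-200.0, 1101.0)
        s = ck.component_waveform(times, (500.0, 1000.0))
        mask = (times >= 500) & (times <= 1000)
        assert s[mask].mean() == pytest.approx(1.0, abs=1e-12)
        assert s[times < 450].max() == 0.0

    def test_missing_analysis_channel_raises(self, tiny_task, flat_participant):
        table = ck.simulate_trial_table(tiny_task, seed=0)
        eeg = ck.EEGSimConfig(channels=("P7", "P8", "HEOG"))
        with pytest.raises(ValueError, match="P10"):
            ck.simulate_epochs(table, flat_participant, eeg)

    def test_determinism(self, tiny_task, flat_participant):
        table = ck.simulate_trial_table(tiny_task, seed=0)
        eeg = ck.EEGSimConfig(noise_sd=3.0)
        a = ck.simulate_epochs(table, flat_participant, eeg, seed=5)
        b = ck.simulate_epochs(table, flat_participant, eeg, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_ar1_noise_has_requested_stationary_sd(self, tiny_task, flat_participant):
        table = ck.simulate_trial_table(tiny_task, seed=0)
        eeg = ck.EEGSimConfig(noise_sd=10.0, noise_model="ar1", sampling_rate=250.0)
        ep = ck.simulate_epochs(table, flat_participant, eeg, seed=6)
        sd = ep.get("Pz").std()
        assert sd == pytest.approx(10.0, rel=0.15)


class TestArtifacts:
    def test_zero_rates_flag_nothing(self, noisefree_epochs):
        epochs, _ = noisefree_epochs
        eeg = ck.EEGSimConfig(saccade_rate=0.0, blast_rate=0.0)
        out, flags = ck.inject_artifacts(epochs, eeg, seed=0)
        assert not flags.any().any()
        assert np.array_equal(out.data, epochs.data)

    def test_flag_counts_are_reproducible_binomial_draws(self, noisefree_epochs):
        epochs, _ = noisefree_epochs
        eeg = ck.EEGSimConfig(saccade_rate=0.1)
        _, f1 = ck.inject_artifacts(epochs, eeg, seed=7)
        _, f2 = ck.inject_artifacts(epochs, eeg, seed=7)
        assert f1.equals(f2)
        assert 0 < f1["saccade"].sum() < len(f1)

    def test_injected_saccades_exceed_heog_threshold(self, noisefree_epochs):
        epochs, _ = noisefree_epochs
        eeg = ck.EEGSimConfig(saccade_rate=0.3, saccade_amp=100.0)
        out, flags = ck.inject_artifacts(epochs, eeg, seed=8)
        from cdakit.artifacts import flag_heog

        assert np.array_equal(flag_heog(out), flags["saccade"].to_numpy())


class TestNoiseCalibration:
    def test_window_mean_level_sd_is_achieved(self):
        """Calibrated per-sample SD yields the target estimator-level SD."""
        from scipy import signal

        from cdakit.preprocess import design_lowpass_fir

        kernel = design_lowpass_fir(17.0, 1000.0)
        target = 2.0
        sigma = ck.calibrate_noise_sd(target, kernel=kernel)
        rng = np.random.default_rng(3)
        t = -200.0 + np.arange(1301)
        win = (t >= 500) & (t <= 1000)
        base = (t >= -200) & (t <= 0)
        x = rng.normal(0, sigma, (1500, 6, t.size))
        xf = signal.fftconvolve(x, kernel[None, None, :], mode="same", axes=-1)
        xf -= xf[:, :, base].mean(-1, keepdims=True)
        d = xf[:, :3].mean(1) - xf[:, 3:].mean(1)
        sd = d[:, win].mean(-1).std(ddof=1)
        assert sd == pytest.approx(target, rel=0.08)

    def test_no_filter_reduces_to_closed_form(self):
        sigma = ck.calibrate_noise_sd(2.0, n_pairs=3)
        expected = 2.0 / np.sqrt(2.0 / 3.0 * (1 / 501 + 1 / 201))
        assert sigma == pytest.approx(expected, rel=1e-12)


def test_balanced_bools_rejects_non_integer_split():
    with pytest.raises(ValueError, match="counterbalance"):
        _balanced_bools(5, 0.5, "change trials")
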
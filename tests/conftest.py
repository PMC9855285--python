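"""Shared fixtures: small synthetic configurations that keep tests fast."""

import dataclasses

import numpy as np
import pytest

import cdakit as ck


@pytest.fixture
def tiny_task():
    """12 trials per condition, divisible into 4 blocks."""
    return ck.TaskConfig(n_trials_per_condition=12, n_blocks=4, vwm_task_trials=20)


@pytest.fixture
def short_eeg():
    """250-Hz, short-epoch EEG config: fast but still covers all windows."""
    return ck.EEGSimConfig(sampling_rate=250.0, noise_sd=5.0)


@pytest.fixture
def flat_participant():
    """Participant with -1 µV ground truth in every condition."""
    return ck.ParticipantRecord(
        id="p1", group="control", bdi=2.0, dass_a=1.0, true_k=3.0,
        ground_truth_cda={c: -1.0 for c in ck.CONDITIONS})


@pytest.fixture
def noisefree_epochs(tiny_task, flat_participant):
    table = ck.simulate_trial_table(tiny_task, seed=11)
    eeg = ck.EEGSimConfig(noise_sd=0.0)
    return ck.simulate_epochs(table, flat_participant, eeg, seed=12), table


@pytest.fixture
def small_study_config(tiny_task):
    return ck.StudyConfig(n_per_group=3, master_seed=5, task=tiny_task,
                          noise_wm_sd=2.0)
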
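"""Synthetic cohorts, trial tables, behaviour and epoched EEG.

This module simulates the study design end to end so that the whole analysis
chain runs without any recorded data: two participant groups (depressed /
control) with distinct questionnaire-score distributions, a lateralized
colour change-detection task (3 conditions x 200 trials, exactly
counterbalanced cue side and change occurrence), slots-model behavioural
responses, and epoched EEG carrying a known contralateral-minus-ipsilateral
component plus ocular and high-amplitude artifacts.

Ground truth is always available: the injected lateralized amplitude per
condition, the true capacity behind each response set, and the trials that
received artifacts.  Every function is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CONDITIONS, GROUPS, EpochSet

__all__ = [
    "GroupParams",
    "ParticipantRecord",
    "CohortSpec",
    "TaskConfig",
    "EEGSimConfig",
    "DEFAULT_GROUP_PARAMS",
    "make_cohort",
    "simulate_trial_table",
    "simulate_behavior",
    "simulate_vwm_task",
    "component_waveform",
    "simulate_epochs",
    "inject_artifacts",
    "calibrate_noise_sd",
]


# ---------------------------------------------------------------------------
# cohort

@dataclass(frozen=True)
class GroupParams:
    """Score and ground-truth distributions for one participant group.

    Questionnaire scores are sampled from normals truncated to the group's
    inclusion range (BDI-II >= 14 for the depressed group, <= 9 for controls).
    ``cda`` maps condition -> mean injected contralateral-minus-ipsilateral
    amplitude in µV; ``cda_sd`` is the between-participant SD around it.
    """

    bdi_mean: float
    bdi_sd: float
    bdi_range: tuple[float, float]
    dass_mean: float
    dass_sd: float
    dass_range: tuple[float, float] = (0.0, 42.0)
    k_mean: float = 2.5
    k_sd: float = 0.8
    k_range: tuple[float, float] = (0.0, 6.0)
    cda: Mapping[str, float] = field(default_factory=dict)
    cda_sd: float = 0.5


#: Defaults follow the study's group descriptions: questionnaire means/SDs and
#: the group x condition CDA amplitudes used as injection targets.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "depressed": GroupParams(
        bdi_mean=26.83, bdi_sd=6.76, bdi_range=(14.0, 63.0),
        dass_mean=8.0, dass_sd=4.17,
        k_mean=2.42, k_sd=0.688,
        cda={"non_dis": -0.68, "fearful_dis": -0.71, "sad_dis": -0.80},
    ),
    "control": GroupParams(
        bdi_mean=2.56, bdi_sd=1.79, bdi_range=(0.0, 9.0),
        dass_mean=1.83, dass_sd=2.77,
        k_mean=2.66, k_sd=1.005,
        cda={"non_dis": -0.42, "fearful_dis": -0.85, "sad_dis": -0.67},
    ),
}


@dataclass
class ParticipantRecord:
    id: str
    group: str
    bdi: float
    dass_a: float
    true_k: float
    ground_truth_cda: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.bdi < 0 or self.dass_a < 0:
            raise ValueError("questionnaire scores must be non-negative")
        if not 0.0 <= self.true_k <= 6.0:
            raise ValueError(f"true_k must lie in [0, 6]; got {self.true_k}")


@dataclass
class CohortSpec:
    participants: list[ParticipantRecord]
    seed: int

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant IDs must be unique")

    def group(self, name: str) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.group == name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row = {"participant": p.id, "group": p.group, "bdi": p.bdi,
                   "dass_a": p.dass_a, "true_k": p.true_k}
            row.update({f"cda_{c}": p.ground_truth_cda[c] for c in CONDITIONS})
            rows.append(row)
        return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if not lo <= mean <= hi:
        raise ValueError(f"mean {mean} outside truncation range [{lo}, {hi}]")
    if sd == 0:
        return np.full(size, float(mean))
    out = np.empty(size)
    n = 0
    while n < size:  # rejection sampling; ranges are wide, acceptance is high
        draw = rng.normal(mean, sd, size=2 * (size - n) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - n)
        out[n:n + take] = draw[:take]
        n += take
    return out


def make_cohort(n_per_group: int,
                group_params: Mapping[str, GroupParams] | None = None,
                seed: int = 0) -> CohortSpec:
    """Sample a two-group cohort with group-specific score distributions.

    The BDI-II inclusion ranges of the two groups must not overlap (they
    define group membership); an overlapping configuration is rejected.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    params = dict(DEFAULT_GROUP_PARAMS if group_params is None else group_params)
    ranges = [params[g].bdi_range for g in GROUPS]
    (lo1, hi1), (lo2, hi2) = ranges
    if max(lo1, lo2) <= min(hi1, hi2):
        raise ValueError(
            f"BDI inclusion ranges of the groups overlap ({ranges}); groups would not be separable"
        )
    rng = np.random.default_rng(seed)
    participants: list[ParticipantRecord] = []
    for group in GROUPS:
        gp = params[group]
        bdi = _truncated_normal(rng, gp.bdi_mean, gp.bdi_sd, *gp.bdi_range, size=n_per_group)
        dass = _truncated_normal(rng, gp.dass_mean, gp.dass_sd, *gp.dass_range, size=n_per_group)
        ks = _truncated_normal(rng, gp.k_mean, gp.k_sd, *gp.k_range, size=n_per_group)
        amps = {c: rng.normal(gp.cda[c], gp.cda_sd, size=n_per_group) for c in CONDITIONS}
        prefix = "dep" if group == "depressed" else "con"
        for i in range(n_per_group):
            participants.append(ParticipantRecord(
                id=f"{prefix}{i + 1:02d}", group=group,
                bdi=float(bdi[i]), dass_a=float(dass[i]), true_k=float(ks[i]),
                ground_truth_cda={c: float(amps[c][i]) for c in CONDITIONS},
            ))
    return CohortSpec(participants=participants, seed=seed)


# ---------------------------------------------------------------------------
# task / trial table

@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the face-filtering task and the capacity task."""

    n_trials_per_condition: int = 200
    conditions: tuple[str, ...] = CONDITIONS
    change_rate: float = 0.5
    cue_balance: float = 0.5
    n_blocks: int = 12
    set_size_targets: int = 2          # colour squares per hemifield
    vwm_task_set_size: int = 6
    vwm_task_trials: int = 100

    @property
    def n_trials_total(self) -> int:
        return self.n_trials_per_condition * len(self.conditions)


def _balanced_bools(n: int, rate: float, what: str) -> np.ndarray:
    k = n * rate
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"cannot exactly counterbalance {what}: {n} trials at rate {rate} "
            f"gives a non-integer count {k}"
        )
    k = int(round(k))
    return np.r_[np.ones(k, bool), np.zeros(n - k, bool)]


def simulate_trial_table(task: TaskConfig = TaskConfig(), seed: int = 0) -> pd.DataFrame:
    """Build one participant's trial table with exact counterbalancing.

    Within each condition the change/no-change split follows ``change_rate``
    exactly and cue sides are balanced within each change class (so both
    margins are exact for even class sizes and off by at most one otherwise).
    Trials are then shuffled and cut into ``n_blocks`` equal blocks.
    """
    n = task.n_trials_per_condition
    total = task.n_trials_total
    if total % task.n_blocks != 0:
        raise ValueError(
            f"{total} trials cannot be split into {task.n_blocks} equal blocks"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for cond in task.conditions:
        change = _balanced_bools(n, task.change_rate, f"change trials in condition {cond!r}")
        cue = np.empty(n, object)
        flip = bool(rng.integers(2))  # which class gets the extra 'left' on odd splits
        for cls, extra_left in ((True, flip), (False, not flip)):
            idx = np.flatnonzero(change == cls)
            m = len(idx)
            k_exact = m * task.cue_balance
            if abs(k_exact - round(k_exact)) < 1e-9:
                k = int(round(k_exact))
            else:
                k = int(np.ceil(k_exact)) if extra_left else int(np.floor(k_exact))
            sides = np.array(["left"] * k + ["right"] * (m - k), object)
            rng.shuffle(sides)
            cue[idx] = sides
        rows.append(pd.DataFrame({
            "condition": cond, "cue_side": cue, "change_present": change,
        }))
    table = pd.concat(rows, ignore_index=True)
    perm = rng.permutation(total)
    table = table.iloc[perm].reset_index(drop=True)
    table.insert(0, "trial_id", np.arange(total))
    table["block"] = np.arange(total) // (total // task.n_blocks)
    return table


# ---------------------------------------------------------------------------
# behaviour (slots model)

def simulate_behavior(true_k: float, set_size: int, guess_rate: float = 0.5,
                      lapse: float = 0.0,
                      trial_table_or_n: pd.DataFrame | int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Append slots-model change-detection responses to a trial table.

    Under the slots model, ``true_k`` of the ``set_size`` items are stored.
    On change trials the probed change is detected with probability
    ``min(true_k/set_size, 1)``; otherwise (and on no-change trials where the
    probed item is unstored) the observer guesses "change" with probability
    ``guess_rate``.  A lapse replaces the response with a fair coin flip.
    With no lapses, E[K-hat] = N x (H - F) = true_k for any guess rate.
    """
    if not 0.0 <= true_k <= set_size:
        raise ValueError(f"true_k must lie in [0, {set_size}]")
    for name, p in (("guess_rate", guess_rate), ("lapse", lapse)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability")
    if isinstance(trial_table_or_n, int):
        n = trial_table_or_n
        change = _balanced_bools(n, 0.5, "change trials")
        table = pd.DataFrame({"trial_id": np.arange(n), "change_present": change})
    else:
        table = trial_table_or_n.copy()
    rng = np.random.default_rng(seed)
    n = len(table)
    change = table["change_present"].to_numpy(dtype=bool)
    stored = rng.random(n) < true_k / set_size
    guess = rng.random(n) < guess_rate
    resp = np.where(change, stored | guess, ~stored & guess)
    lapsed = rng.random(n) < lapse
    coin = rng.random(n) < 0.5
    resp = np.where(lapsed, coin, resp)
    table["response_change"] = resp
    table["correct"] = resp == change
    return table


def simulate_vwm_task(true_k: float, n_trials: int = 100, set_size: int = 6,
                      guess_rate: float = 0.5, lapse: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """One participant's capacity-measurement run (single-probe, 50% change)."""
    return simulate_behavior(true_k, set_size, guess_rate, lapse, n_trials, seed)


# ---------------------------------------------------------------------------
# EEG

@dataclass(frozen=True)
class EEGSimConfig:
    """Parameters of the epoched-EEG simulator.

    ``noise_sd`` is the per-sample noise SD in µV (see
    :func:`calibrate_noise_sd` to target a window-mean-level SD instead).
    The lateralized component is a plateau spanning ``component_window`` with
    50-ms raised-cosine ramps outside it, so its window mean equals the
    requested amplitude exactly.  ``bilateral_amp`` scales a common
    (non-lateralized) deflection of the same shape added to all analysis
    sites; it cancels in the contra-minus-ipsi difference.
    """

    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-200.0, 1100.0)
    channels: tuple[str, ...] = ("P7", "P9", "PO7", "P8", "P10", "PO8", "Pz", "Oz", "HEOG")
    left_sites: tuple[str, ...] = ("P7", "P9", "PO7")
    right_sites: tuple[str, ...] = ("P8", "P10", "PO8")
    heog_channel: str = "HEOG"
    noise_sd: float = 20.0
    noise_model: str = "white"         # "white" | "ar1"
    ar1_phi: float = 0.97
    component_window: tuple[float, float] = (500.0, 1000.0)
    ramp_ms: float = 50.0
    bilateral_amp: float = -1.0
    saccade_rate: float = 0.0
    saccade_amp: float = 100.0
    blast_rate: float = 0.0
    blast_amp: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("white", "ar1"):
            raise ValueError("noise_model must be 'white' or 'ar1'")
        lo, hi = self.epoch_window
        wlo, whi = self.component_window
        if not (lo <= wlo < whi <= hi):
            raise ValueError("component window must lie inside the epoch window")
        if not (lo <= -0.0 <= hi):
            raise ValueError("epoch window must cover the baseline and stimulus onset")

    @property
    def times(self) -> np.ndarray:
        lo, hi = self.epoch_window
        n = int(round((hi - lo) * self.sampling_rate / 1000.0)) + 1
        return lo + np.arange(n) * 1000.0 / self.sampling_rate


def component_waveform(times: np.ndarray, window: tuple[float, float],
                       ramp_ms: float = 50.0) -> np.ndarray:
    """Unit plateau over ``window`` with raised-cosine on/off ramps outside it.

    The mean over [window[0], window[1]] (inclusive) equals 1 exactly, so an
    amplitude-scaled copy has that amplitude as its window mean.
    """
    lo, hi = window
    s = np.zeros_like(times, dtype=float)
    s[(times >= lo) & (times <= hi)] = 1.0
    if ramp_ms > 0:
        up = (times >= lo - ramp_ms) & (times < lo)
        s[up] = 0.5 * (1 - np.cos(np.pi * (times[up] - (lo - ramp_ms)) / ramp_ms))
        down = (times > hi) & (times <= hi + ramp_ms)
        s[down] = 0.5 * (1 + np.cos(np.pi * (times[down] - hi) / ramp_ms))
    return s


def _noise(rng: np.random.Generator, cfg: EEGSimConfig, shape: tuple[int, ...]) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(shape)
    if cfg.noise_model == "white":
        return rng.normal(0.0, cfg.noise_sd, shape)
    # AR(1): innovations scaled for a stationary per-sample SD of noise_sd
    phi = cfg.ar1_phi
    innov = rng.normal(0.0, cfg.noise_sd * np.sqrt(1 - phi ** 2), shape)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, cfg.noise_sd, shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + innov[..., t]
    return out


def simulate_epochs(trial_table: pd.DataFrame, participant: ParticipantRecord,
                    eeg: EEGSimConfig = EEGSimConfig(),
                    seed: int | None = None) -> EpochSet:
    """Synthesize epoched EEG for one participant's trial table.

    Per trial, the three sites contralateral to the cued hemifield receive a
    sustained deflection whose contra-minus-ipsi window mean equals the
    participant's ``ground_truth_cda`` for that trial's condition; a common
    bilateral deflection is added to all six sites.  The HEOG channel is flat
    (artifacts are injected separately by :func:`inject_artifacts`).
    """
    required = set(eeg.left_sites) | set(eeg.right_sites) | {eeg.heog_channel}
    missing = sorted(required - set(eeg.channels))
    if missing:
        raise ValueError(f"EEG config lacks required analysis channels: {missing}")
    rng = np.random.default_rng(eeg.seed if seed is None else seed)
    times = eeg.times
    n_trials = len(trial_table)
    n_ch = len(eeg.channels)
    data = _noise(rng, eeg, (n_trials, n_ch, times.size))
    heog_idx = eeg.channels.index(eeg.heog_channel)
    data[:, heog_idx, :] = 0.0

    shape = component_waveform(times, eeg.component_window, eeg.ramp_ms)
    left_idx = [eeg.channels.index(c) for c in eeg.left_sites]
    right_idx = [eeg.channels.index(c) for c in eeg.right_sites]
    cue = trial_table["cue_side"].to_numpy()
    cond = trial_table["condition"].to_numpy()
    for i in range(n_trials):
        amp = participant.ground_truth_cda[cond[i]]
        contra = right_idx if cue[i] == "left" else left_idx
        data[i, left_idx, :] += eeg.bilateral_amp * shape
        data[i, right_idx, :] += eeg.bilateral_amp * shape
        data[i, contra, :] += amp * shape
    return EpochSet(data=data, channel_names=list(eeg.channels),
                    sfreq=eeg.sampling_rate, tmin=eeg.epoch_window[0])


def inject_artifacts(epochs: EpochSet, eeg: EEGSimConfig,
                     seed: int = 0) -> tuple[EpochSet, pd.DataFrame]:
    """Add saccade (HEOG) and high-amplitude (scalp) artifacts to flagged trials.

    Returns the contaminated copy and a ground-truth flag table with boolean
    columns ``saccade`` and ``blast`` for oracle testing of the rejection
    stage.  Saccades are steps of ±``saccade_amp`` µV on the HEOG channel from
    a random post-onset latency onward; blasts are 100-ms boxcar excursions of
    ±``blast_amp`` µV on one random scalp channel.
    """
    for name, p in (("saccade_rate", eeg.saccade_rate), ("blast_rate", eeg.blast_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability")
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    n = out.n_trials
    heog = out.channel_index(eeg.heog_channel)
    scalp = [i for i, c in enumerate(out.channel_names) if c != eeg.heog_channel]
    times = out.times
    saccade = rng.random(n) < eeg.saccade_rate
    blast = rng.random(n) < eeg.blast_rate
    for i in range(n):
        if saccade[i]:
            onset = rng.uniform(0.0, times[-1] * 0.7)
            sign = rng.choice([-1.0, 1.0])
            out.data[i, heog, times >= onset] += sign * eeg.saccade_amp
        if blast[i]:
            ch = int(rng.choice(scalp))
            onset = rng.uniform(times[0], times[-1] - 100.0)
            sign = rng.choice([-1.0, 1.0])
            mask = (times >= onset) & (times < onset + 100.0)
            out.data[i, ch, mask] += sign * eeg.blast_amp
    flags = pd.DataFrame({"saccade": saccade, "blast": blast})
    return out, flags


def calibrate_noise_sd(window_mean_sd: float,
                       n_pairs: int = 3,
                       times: np.ndarray | None = None,
                       window: tuple[float, float] = (500.0, 1000.0),
                       baseline: tuple[float, float] = (-200.0, 0.0),
                       kernel: np.ndarray | None = None) -> float:
    """Per-sample white-noise SD giving a target single-trial CDA-estimate SD.

    ``window_mean_sd`` is the SD, across trials, of the single-trial
    contra-minus-ipsi window mean as produced by the measuring chain
    (site averaging over ``n_pairs`` pairs, optional zero-phase FIR ``kernel``,
    baseline correction, inclusive window mean).  For white per-sample noise
    of SD sigma that estimate has variance

        (2 / n_pairs) * sigma^2 * ||h (*) (b_win - b_base)||^2

    with b_* the boxcar averaging weights restricted to the epoch support
    (the average reference cancels in the difference and is ignored).
    """
    if times is None:
        times = -200.0 + np.arange(1301)
    t = np.asarray(times, float)

    def eff(mask: np.ndarray) -> np.ndarray:
        b = mask.astype(float) / mask.sum()
        if kernel is None:
            return b
        w = np.convolve(b, kernel)
        off = (len(kernel) - 1) // 2
        return w[off:off + t.size]

    w_win = eff((t >= window[0] - 1e-9) & (t <= window[1] + 1e-9))
    w_base = eff((t >= baseline[0] - 1e-9) & (t <= baseline[1] + 1e-9))
    gain = float(np.sum((w_win - w_base) ** 2))
    return window_mean_sd / np.sqrt(2.0 / n_pairs * gain)
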
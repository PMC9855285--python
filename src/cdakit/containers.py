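"""Core in-memory containers: epoched EEG arrays and per-trial task tables.

An :class:`EpochSet` is a single participant's epoched EEG as a
``(n_trials, n_channels, n_times)`` array in microvolts, with channel names,
sampling rate and a millisecond time axis.  A trial table is a plain
:class:`pandas.DataFrame` with one row per trial; :func:`validate_trial_table`
checks the column contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

#: The three task conditions of the face-filtering change-detection design:
#: colour squares alone, with fearful face distractors, with sad face distractors.
CONDITIONS: tuple[str, ...] = ("non_dis", "fearful_dis", "sad_dis")

CUE_SIDES: tuple[str, ...] = ("left", "right")

GROUPS: tuple[str, ...] = ("depressed", "control")

#: Columns every trial table must carry.  ``response_change`` / ``correct``
#: appear once behavioural responses exist; rejection flags once artifact
#: screening has run.
TRIAL_TABLE_COLUMNS = ("trial_id", "condition", "cue_side", "change_present", "block")
OPTIONAL_TRIAL_COLUMNS = ("response_change", "correct", "rejected_heog", "rejected_amp")


@dataclass
class EpochSet:
    """Epoched multichannel EEG for one participant, in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Epoch voltages in µV.
    channel_names : sequence of str
        Unique channel labels, one per channel row.
    sfreq : float
        Sampling rate in Hz.
    tmin : float
        Time of the first sample in ms relative to memory-array onset
        (negative for pre-stimulus samples).
    """

    data: np.ndarray
    channel_names: list[str]
    sfreq: float
    tmin: float = -200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(
                f"EpochSet.data must be (n_trials, n_channels, n_times); got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"channel axis has {self.data.shape[1]} rows but {len(self.channel_names)} names given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms (sample at t=0 included when tmin <= 0 <= tmax)."""
        return self.tmin + np.arange(self.n_times) * 1000.0 / self.sfreq

    @property
    def time_zero_index(self) -> int:
        """Index of the sample at stimulus onset (t = 0 ms)."""
        idx = int(np.argmin(np.abs(self.times)))
        if abs(self.times[idx]) > 1e-6:
            raise ValueError("epoch window does not contain t = 0")
        return idx

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in EpochSet ({self.channel_names})") from None

    def get(self, name: str) -> np.ndarray:
        """Return (n_trials, n_times) data for one channel."""
        return self.data[:, self.channel_index(name), :]

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), channel_names=list(self.channel_names))

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask over samples with time in [start, end] ms, inclusive."""
        lo, hi = window
        if hi < lo:
            raise ValueError(f"window start {lo} must not exceed end {hi}")
        t = self.times
        mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} ms contains no samples of the epoch time axis")
        return mask


def validate_trial_table(table: pd.DataFrame, require_responses: bool = False) -> None:
    """Check a trial table against the column/enum contract.

    Raises ``ValueError`` naming the offending column or label.
    """
    if len(table) == 0:
        raise ValueError("trial table is empty")
    for col in TRIAL_TABLE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"trial table missing required column {col!r}")
    if require_responses:
        for col in ("response_change", "correct"):
            if col not in table.columns:
                raise ValueError(f"trial table missing required column {col!r}")
    bad_cond = set(table["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(
            f"unknown condition label(s) {sorted(bad_cond)!r}; expected one of {CONDITIONS}"
        )
    bad_side = set(table["cue_side"].unique()) - set(CUE_SIDES)
    if bad_side:
        raise ValueError(f"unknown cue_side label(s) {sorted(bad_side)!r}; expected one of {CUE_SIDES}")
    if "response_change" in table.columns and "correct" in table.columns:
        resp = table["response_change"].to_numpy(dtype=bool)
        chg = table["change_present"].to_numpy(dtype=bool)
        corr = table["correct"].to_numpy(dtype=bool)
        if not np.array_equal(corr, resp == chg):
            raise ValueError("column 'correct' inconsistent with response_change == change_present")
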
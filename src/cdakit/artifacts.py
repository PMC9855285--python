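"""Trial-level artifact flagging and participant-level exclusion.

Two independent criteria mirror standard lateralized-ERP practice: trials
with horizontal-EOG excursions beyond ±60 µV (lateral eye movements break the
contralateral/ipsilateral assignment) and trials with any scalp-channel
excursion beyond ±80 µV.  Participants whose combined rejection rate exceeds
30% are excluded.  Both thresholds use strict inequality on the epoch
extremum (peak-based; a peak-to-peak variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CONDITIONS, CUE_SIDES, EpochSet

__all__ = [
    "RejectionPolicy",
    "flag_heog",
    "flag_amplitude",
    "apply_flags",
    "exclude_participants",
    "rejection_rate_table",
]


@dataclass(frozen=True)
class RejectionPolicy:
    heog_threshold: float = 60.0
    amp_threshold: float = 80.0
    participant_max_rejection: float = 0.30
    heog_channel: str = "HEOG"
    scalp_channels: tuple[str, ...] | None = None  # None -> all except HEOG
    peak_to_peak: bool = False

    def __post_init__(self) -> None:
        if self.heog_threshold <= 0 or self.amp_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.participant_max_rejection <= 1.0:
            raise ValueError("participant_max_rejection must lie in (0, 1]")


def _exceeds(x: np.ndarray, threshold: float, peak_to_peak: bool) -> np.ndarray:
    """Per-trial flag: does any channel exceed the criterion over the epoch?"""
    if peak_to_peak:
        stat = x.max(axis=-1) - x.min(axis=-1)
    else:
        stat = np.abs(x).max(axis=-1)
    return (stat > threshold).any(axis=-1) if stat.ndim > 1 else stat > threshold


def flag_heog(epochs: EpochSet, policy: RejectionPolicy = RejectionPolicy()) -> np.ndarray:
    """Flag trials whose |HEOG| exceeds the threshold anywhere in the epoch."""
    heog = epochs.get(policy.heog_channel)  # KeyError with channel name if absent
    return _exceeds(heog, policy.heog_threshold, policy.peak_to_peak)


def flag_amplitude(epochs: EpochSet, policy: RejectionPolicy = RejectionPolicy()) -> np.ndarray:
    """Flag trials with any scalp-channel excursion beyond the amplitude threshold.

    Flags are computed for every trial (independently of the HEOG criterion)
    so that rule-specific rejection counts can be reported separately; a
    trial rejected by either rule is removed from ERP averaging.
    """
    if policy.scalp_channels is None:
        names = [c for c in epochs.channel_names if c != policy.heog_channel]
    else:
        names = list(policy.scalp_channels)
    if not names:
        raise ValueError("no scalp channels to apply the amplitude criterion to")
    idx = [epochs.channel_index(c) for c in names]
    return _exceeds(epochs.data[:, idx, :], policy.amp_threshold, policy.peak_to_peak)


def apply_flags(table: pd.DataFrame, heog_flags: np.ndarray,
                amp_flags: np.ndarray) -> pd.DataFrame:
    """Return a copy of the trial table with rejection-flag columns set."""
    if len(table) != len(heog_flags) or len(table) != len(amp_flags):
        raise ValueError("flag arrays must match the trial table length")
    out = table.copy()
    out["rejected_heog"] = np.asarray(heog_flags, bool)
    out["rejected_amp"] = np.asarray(amp_flags, bool)
    return out


def exclude_participants(rejection_rates: Mapping[str, float] | pd.Series,
                         policy: RejectionPolicy = RejectionPolicy()) -> tuple[list[str], list[str]]:
    """Split participants into (included, excluded) by overall rejection rate.

    Exclusion is strict: a rate exactly at the cap (30%) is retained.
    """
    rates = pd.Series(rejection_rates, dtype=float)
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("rejection rates must lie in [0, 1]")
    excluded = rates.index[rates > policy.participant_max_rejection].tolist()
    included = rates.index[rates <= policy.participant_max_rejection].tolist()
    return included, excluded


def rejection_rate_table(tables: pd.DataFrame,
                         flag_col: str = "rejected_heog") -> pd.DataFrame:
    """Per-cell rejection rates for the condition x cue-side x participant design.

    ``tables`` is a concatenated trial table with a ``participant`` column and
    populated flag columns.  Empty cells yield a missing (NaN) rate.
    """
    if flag_col not in tables.columns:
        raise ValueError(f"trial table has no flag column {flag_col!r}")
    if "participant" not in tables.columns:
        raise ValueError("need a 'participant' column to compute per-participant rates")
    grouped = tables.groupby(["participant", "condition", "cue_side"], observed=True)[flag_col]
    agg = grouped.agg(n_flagged="sum", n_trials="size")
    participants = tables["participant"].unique()
    full = pd.MultiIndex.from_product([participants, CONDITIONS, CUE_SIDES],
                                      names=["participant", "condition", "cue_side"])
    agg = agg.reindex(full)
    agg["rate"] = agg["n_flagged"] / agg["n_trials"]
    return agg.reset_index()
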
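"""Lateralized ERP measures: contralateral/ipsilateral waves, CDA amplitudes.

The contralateral waveform averages activity at electrodes opposite the cued
hemifield (left-hemisphere sites on cue-right trials and vice versa); the
ipsilateral waveform uses the complementary assignment.  Their difference
over the 500-1000-ms retention window is the contralateral delay activity
(CDA), an amplitude that scales with the number of items held in visual
working memory.  Subtracting the no-distractor baseline condition gives a
difference score whose negative values indicate extra storage attributable
to distractors (a filtering failure).

Averaging order is trials (within cue side) -> sites -> the two cue sides
weighted equally, so unequal trial rejection across cue sides cannot bias
the contra/ipsi comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "Montage",
    "AnalysisWindows",
    "LateralizedMeasure",
    "contra_ipsi_waves",
    "window_mean",
    "cda_difference_score",
    "measure_condition",
    "grand_average",
]


@dataclass(frozen=True)
class Montage:
    """Left/right electrode pairs entering the lateralized average."""

    pairs: tuple[tuple[str, str], ...] = (("P7", "P8"), ("P9", "P10"), ("PO7", "PO8"))

    def __post_init__(self) -> None:
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("montage pairs must be disjoint")

    @property
    def left_sites(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def right_sites(self) -> tuple[str, ...]:
        return tuple(p[1] for p in self.pairs)

    def validate(self, epochs: EpochSet) -> None:
        missing = [s for s in self.left_sites + self.right_sites
                   if s not in epochs.channel_names]
        if missing:
            raise ValueError(f"montage sites missing from the data: {missing}")


@dataclass(frozen=True)
class AnalysisWindows:
    """Measurement windows in ms after memory-array onset.

    ``cda`` is the retention-interval window.  ``extra`` holds exploratory
    earlier components measured with the same operator; the default N2pc and
    Ppc windows are conventional placeholders, not calibrated values, and
    should be set explicitly for any substantive use.
    """

    cda: tuple[float, float] = (500.0, 1000.0)
    extra: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"n2pc": (200.0, 300.0), "ppc": (100.0, 200.0)})

    def __post_init__(self) -> None:
        for name, (lo, hi) in {"cda": self.cda, **dict(self.extra)}.items():
            if lo >= hi:
                raise ValueError(f"window {name!r} must have start < end")


@dataclass
class LateralizedMeasure:
    """Contra/ipsi waveforms and window-mean amplitudes for one condition."""

    condition: str
    times: np.ndarray
    contra_wave: np.ndarray
    ipsi_wave: np.ndarray
    cda_amplitude: float
    extra_amplitudes: dict[str, float]
    n_trials_used: int

    @property
    def diff_wave(self) -> np.ndarray:
        return self.contra_wave - self.ipsi_wave


def _usable(table: pd.DataFrame) -> np.ndarray:
    keep = np.ones(len(table), bool)
    for col in ("rejected_heog", "rejected_amp"):
        if col in table.columns:
            keep &= ~table[col].to_numpy(dtype=bool)
    return keep


def contra_ipsi_waves(epochs: EpochSet, table: pd.DataFrame, montage: Montage,
                      condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Average contralateral and ipsilateral waveforms for one condition.

    Uses all unrejected trials of the condition.  Raises if either cue side
    has no usable trial (the two sides are averaged with equal weight, so
    both must be represented).
    """
    montage.validate(epochs)
    if condition not in set(table["condition"]):
        raise ValueError(f"condition {condition!r} not present in the trial table")
    left_idx = [epochs.channel_index(c) for c in montage.left_sites]
    right_idx = [epochs.channel_index(c) for c in montage.right_sites]
    keep = _usable(table) & (table["condition"] == condition).to_numpy()
    cue = table["cue_side"].to_numpy()
    side_means = {}
    for side in ("left", "right"):
        sel = keep & (cue == side)
        if not sel.any():
            raise ValueError(
                f"no usable trials for condition {condition!r}, cue side {side!r}")
        side_means[side] = epochs.data[sel].mean(axis=0)  # channels x time
    contra = 0.5 * (side_means["left"][right_idx].mean(axis=0)
                    + side_means["right"][left_idx].mean(axis=0))
    ipsi = 0.5 * (side_means["left"][left_idx].mean(axis=0)
                  + side_means["right"][right_idx].mean(axis=0))
    return contra, ipsi


def window_mean(wave: np.ndarray, times: np.ndarray,
                window: tuple[float, float]) -> float:
    """Mean of samples with time in [start, end] ms, both endpoints inclusive."""
    lo, hi = window
    if lo > hi:
        raise ValueError("window start must not exceed end")
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples")
    return float(np.asarray(wave)[..., mask].mean(axis=-1))


def cda_difference_score(distractor_amp: float, baseline_amp: float) -> float:
    """Distractor-condition CDA minus no-distractor CDA.

    Negative scores mean a larger (more negative) CDA with distractors
    present, i.e. additional working-memory storage of the distractors.
    """
    return float(distractor_amp - baseline_amp)


def measure_condition(epochs: EpochSet, table: pd.DataFrame, montage: Montage,
                      windows: AnalysisWindows, condition: str) -> LateralizedMeasure:
    """Full lateralized measurement for one condition of one participant."""
    contra, ipsi = contra_ipsi_waves(epochs, table, montage, condition)
    times = epochs.times
    diff = contra - ipsi
    keep = _usable(table) & (table["condition"] == condition).to_numpy()
    return LateralizedMeasure(
        condition=condition, times=times, contra_wave=contra, ipsi_wave=ipsi,
        cda_amplitude=window_mean(diff, times, windows.cda),
        extra_amplitudes={name: window_mean(diff, times, w)
                          for name, w in dict(windows.extra).items()},
        n_trials_used=int(keep.sum()),
    )


def grand_average(measures: Sequence[LateralizedMeasure]) -> LateralizedMeasure:
    """Unweighted across-participant mean of waveforms and amplitudes."""
    if not measures:
        raise ValueError("need at least one participant measure")
    conditions = {m.condition for m in measures}
    if len(conditions) != 1:
        raise ValueError(f"cannot grand-average across conditions {sorted(conditions)}")
    extra_keys = measures[0].extra_amplitudes.keys()
    return LateralizedMeasure(
        condition=measures[0].condition,
        times=measures[0].times,
        contra_wave=np.mean([m.contra_wave for m in measures], axis=0),
        ipsi_wave=np.mean([m.ipsi_wave for m in measures], axis=0),
        cda_amplitude=float(np.mean([m.cda_amplitude for m in measures])),
        extra_amplitudes={k: float(np.mean([m.extra_amplitudes[k] for m in measures]))
                          for k in extra_keys},
        n_trials_used=int(np.sum([m.n_trials_used for m in measures])),
    )
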
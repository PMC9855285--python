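"""Behavioural measures: accuracy, hit/false-alarm rates, Cowan's K, d-prime.

For a whole-display change-detection task at set size N, Cowan's K
K = N x (H - F) estimates the number of items held in working memory from
the hit rate H and false-alarm rate F.  d' = Z(H) - Z(F) is the
signal-detection sensitivity, with Z the inverse standard-normal CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .containers import CONDITIONS

__all__ = [
    "BehavioralSummary",
    "accuracy_by_condition",
    "hit_false_alarm",
    "cowan_k",
    "dprime",
    "summarize_vwm",
]


@dataclass
class BehavioralSummary:
    participant: str
    hit_rate: float
    false_alarm_rate: float
    k: float
    d_prime: float
    set_size: int
    n_trials: int


def accuracy_by_condition(table: pd.DataFrame) -> pd.Series:
    """Proportion correct per condition over all responded trials.

    Behavioural accuracy deliberately includes EEG-rejected trials: the
    behavioural and ERP trial sets are analysed independently.
    """
    if "correct" not in table.columns:
        raise ValueError("trial table has no 'correct' column; simulate or load responses first")
    acc = table.groupby("condition", observed=True)["correct"].mean()
    order = [c for c in CONDITIONS if c in acc.index]
    return acc.reindex(order)


def hit_false_alarm(table: pd.DataFrame) -> tuple[float, float]:
    """Hit and false-alarm rates from a change-detection trial table.

    H = proportion of "change" responses on change trials; F = proportion of
    "change" responses on no-change trials.
    """
    change = table["change_present"].to_numpy(dtype=bool)
    resp = table["response_change"].to_numpy(dtype=bool)
    n_change = int(change.sum())
    n_nochange = int((~change).sum())
    if n_change == 0 or n_nochange == 0:
        raise ValueError("need both change and no-change trials to compute H and F")
    hit = float(resp[change].mean())
    fa = float(resp[~change].mean())
    return hit, fa


def cowan_k(hit_rate: float, false_alarm_rate: float, set_size: int = 6) -> float:
    """Cowan's K = N x (H - F); negative estimates are preserved, not clamped."""
    for name, p in (("hit_rate", hit_rate), ("false_alarm_rate", false_alarm_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if set_size < 1:
        raise ValueError("set size must be >= 1")
    return set_size * (hit_rate - false_alarm_rate)


def dprime(hit_rate: float, false_alarm_rate: float,
           n_change: int | None = None, n_nochange: int | None = None,
           correction: str = "half_trial") -> float:
    """d' = Z(H) - Z(F) with an extreme-rate correction.

    ``correction="half_trial"`` replaces a rate of 0 with 1/(2n) and 1 with
    1 - 1/(2n), n being the trial count of that class (the counts are then
    required).  ``correction="none"`` raises on extreme rates, where d'
    would be infinite.
    """
    for name, p in (("hit_rate", hit_rate), ("false_alarm_rate", false_alarm_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rates = [hit_rate, false_alarm_rate]
    ns = [n_change, n_nochange]
    if correction == "none":
        if 0.0 in rates or 1.0 in rates:
            raise ValueError("extreme rate with correction='none' gives infinite d'")
    elif correction == "half_trial":
        for i, (p, n) in enumerate(zip(rates, ns)):
            if p in (0.0, 1.0):
                if n is None:
                    raise ValueError("half-trial correction of an extreme rate needs the trial count")
                rates[i] = 1.0 / (2 * n) if p == 0.0 else 1.0 - 1.0 / (2 * n)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(sps.norm.ppf(rates[0]) - sps.norm.ppf(rates[1]))


def summarize_vwm(table: pd.DataFrame, participant: str = "",
                  set_size: int = 6) -> BehavioralSummary:
    """Per-participant summary of the capacity-measurement run."""
    hit, fa = hit_false_alarm(table)
    change = table["change_present"].to_numpy(dtype=bool)
    return BehavioralSummary(
        participant=participant,
        hit_rate=hit, false_alarm_rate=fa,
        k=cowan_k(hit, fa, set_size),
        d_prime=dprime(hit, fa, int(change.sum()), int((~change).sum())),
        set_size=set_size, n_trials=len(table),
    )
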
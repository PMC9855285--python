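"""Simple waveform and bar plots of fitted study results."""

from __future__ import annotations

import numpy as np

from .containers import CONDITIONS

_COND_LABEL = {"non_dis": "Non-dis", "fearful_dis": "Fearful-dis", "sad_dis": "Sad-dis"}


def plot_difference_waves(results, ax=None, group: str | None = None):
    """Grand-average contra-minus-ipsi difference waves per condition.

    ``results`` is a fitted :class:`~cdakit.model.CDAStudyResults`; one line
    per condition, one panel per group (or a single panel when ``group`` is
    given).  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    ga = results.grand_averages
    groups = [group] if group else sorted({g for g, _ in ga})
    if ax is None:
        fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 3.5),
                                 sharey=True, squeeze=False)
        axes = axes[0]
    else:
        fig, axes = ax.figure, [ax]
    for a, g in zip(axes, groups):
        for cond in CONDITIONS:
            m = ga[(g, cond)]
            a.plot(m.times, m.diff_wave, label=_COND_LABEL[cond])
        a.axvspan(500, 1000, alpha=0.15, color="grey")
        a.axhline(0, lw=0.5, color="k")
        a.axvline(0, lw=0.5, color="k")
        a.set_xlabel("time (ms)")
        a.set_title(g)
        a.legend(fontsize=8)
    axes[0].set_ylabel("contra - ipsi (µV)")
    fig.tight_layout()
    return fig


def plot_condition_bars(results, measure: str = "cda", ax=None):
    """Bar plot of group x condition means with SEM error bars."""
    import matplotlib.pyplot as plt

    t1 = results.table1
    col = {"cda": "cda_mean", "accuracy": "accuracy_mean"}[measure]
    sd_col = col.replace("mean", "sd")
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
    else:
        fig = ax.figure
    groups = sorted(t1["group"].unique())
    n_per = results.per_participant.groupby("group")["participant"].count()
    width = 0.8 / len(groups)
    x = np.arange(len(CONDITIONS))
    for i, g in enumerate(groups):
        sub = t1[t1["group"] == g].set_index("condition").reindex(list(CONDITIONS))
        sem = sub[sd_col] / np.sqrt(n_per[g])
        ax.bar(x + i * width, sub[col], width=width, yerr=sem, capsize=3, label=g)
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels([_COND_LABEL[c] for c in CONDITIONS])
    ax.set_ylabel({"cda": "CDA amplitude (µV)", "accuracy": "accuracy"}[measure])
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
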
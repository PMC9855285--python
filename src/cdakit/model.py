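"""Study-level model object and fitted results.

:class:`CDAStudy` bundles each participant's epoched EEG, filtering-task
trial table, capacity-task responses and cohort record, together with the
analysis options (preprocessing, rejection policy, montage, windows).
:meth:`CDAStudy.fit` runs the full chain — preprocess, flag artifacts,
lateralized measures, behavioural measures, participant exclusion, group
statistics — and returns a :class:`CDAStudyResults` carrying per-participant
records, the group x condition summary table, planned comparisons, omnibus
ANOVA/ANCOVA results, correlations and a formatted ``summary()``.

All group-level tables are derived from the per-participant records alone,
so a report regenerated from persisted records is identical to the original
(see :func:`compute_study_stats`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .artifacts import (RejectionPolicy, apply_flags, exclude_participants,
                        flag_amplitude, flag_heog, rejection_rate_table)
from .behavior import accuracy_by_condition, summarize_vwm
from .containers import CONDITIONS, CUE_SIDES, EpochSet
from .lateralized import (AnalysisWindows, LateralizedMeasure, Montage,
                          cda_difference_score, grand_average, measure_condition)
from .preprocess import PreprocConfig, preprocess
from .simulate import ParticipantRecord
from . import stats as st

logger = logging.getLogger(__name__)

__all__ = ["ParticipantData", "CDAStudy", "CDAStudyResults", "compute_study_stats"]

#: distractor conditions paired against the no-distractor baseline
_DISTRACTORS = ("fearful_dis", "sad_dis")
_PAIRS = (("non_dis", "fearful_dis"), ("non_dis", "sad_dis"), ("fearful_dis", "sad_dis"))


@dataclass
class ParticipantData:
    """One participant's raw inputs to the study model."""

    record: ParticipantRecord
    epochs: EpochSet
    trial_table: pd.DataFrame
    vwm_table: pd.DataFrame
    artifact_truth: pd.DataFrame | None = None  # simulator ground-truth flags


class CDAStudy:
    """Model object for a two-group lateralized change-detection ERP study.

    Parameters
    ----------
    participants : sequence of ParticipantData
    preproc, rejection, montage, windows
        Analysis options; defaults follow the standard chain (17-Hz
        low-pass, ±60/±80 µV rejection, P7/8-P9/10-PO7/8 montage,
        500-1000 ms CDA window).
    neighbor_map : mapping, optional
        Channel adjacency used only when ``preproc.bad_channels`` is set.
    """

    def __init__(self, participants: Sequence[ParticipantData],
                 preproc: PreprocConfig = PreprocConfig(),
                 rejection: RejectionPolicy = RejectionPolicy(),
                 montage: Montage = Montage(),
                 windows: AnalysisWindows = AnalysisWindows(),
                 neighbor_map: Mapping[str, Sequence[str]] | None = None):
        if not participants:
            raise ValueError("need at least one participant")
        self.participants = list(participants)
        self.preproc = preproc
        self.rejection = rejection
        self.montage = montage
        self.windows = windows
        self.neighbor_map = neighbor_map

    @classmethod
    def from_simulation(cls, config) -> "CDAStudy":
        """Build a study from a :class:`cdakit.pipeline.StudyConfig` simulation."""
        from .pipeline import simulate_study

        return simulate_study(config)

    # ------------------------------------------------------------------
    def _measure_participant(self, pdata: ParticipantData
                             ) -> tuple[dict, dict[str, LateralizedMeasure]]:
        rec = pdata.record
        pre = preprocess(pdata.epochs, self.preproc, self.neighbor_map)
        heog = flag_heog(pre, self.rejection)
        amp = flag_amplitude(pre, self.rejection)
        table = apply_flags(pdata.trial_table, heog, amp)
        combined = heog | amp

        row: dict = {
            "participant": rec.id, "group": rec.group,
            "bdi": rec.bdi, "dass_a": rec.dass_a, "true_k": rec.true_k,
            "rej_rate": float(combined.mean()),
            "rej_rate_heog": float(heog.mean()),
            "rej_rate_amp": float(amp.mean()),
        }
        beh = summarize_vwm(pdata.vwm_table, rec.id)
        row.update({"k": beh.k, "d_prime": beh.d_prime,
                    "hit_rate": beh.hit_rate, "fa_rate": beh.false_alarm_rate})
        acc = accuracy_by_condition(table)
        for cond in CONDITIONS:
            row[f"acc_{cond}"] = float(acc[cond])

        measures: dict[str, LateralizedMeasure] = {}
        for cond in CONDITIONS:
            m = measure_condition(pre, table, self.montage, self.windows, cond)
            measures[cond] = m
            row[f"cda_{cond}"] = m.cda_amplitude
            row[f"n_used_{cond}"] = m.n_trials_used
            for name, val in m.extra_amplitudes.items():
                row[f"{name}_{cond}"] = val
        for dis in _DISTRACTORS:
            row[f"diff_{dis}"] = cda_difference_score(row[f"cda_{dis}"], row["cda_non_dis"])

        # HEOG-rule rejection rates per condition x cue-side cell
        cell = table.assign(participant=rec.id)
        rates = rejection_rate_table(cell, "rejected_heog")
        for _, r in rates.iterrows():
            row[f"heograte_{r['condition']}_{r['cue_side']}"] = r["rate"]
        return row, measures

    def fit(self, d_convention: str = "dz") -> "CDAStudyResults":
        """Run the full analysis chain and return fitted results."""
        rows, all_measures = [], {}
        for pdata in self.participants:
            try:
                row, measures = self._measure_participant(pdata)
            except Exception as exc:
                raise RuntimeError(
                    f"analysis failed at participant {pdata.record.id!r}: {exc}") from exc
            rows.append(row)
            all_measures[pdata.record.id] = measures
        pp = pd.DataFrame(rows)

        included, excluded = exclude_participants(
            pp.set_index("participant")["rej_rate"], self.rejection)
        pp["included"] = pp["participant"].isin(included)
        if excluded:
            logger.info("excluded %d participant(s) with rejection rate > %.0f%%: %s",
                        len(excluded), 100 * self.rejection.participant_max_rejection,
                        excluded)
        stats = compute_study_stats(pp, d_convention=d_convention)

        ga = {}
        inc = set(included)
        for group in sorted(pp["group"].unique()):
            ids = pp.loc[(pp["group"] == group) & pp["included"], "participant"]
            for cond in CONDITIONS:
                ga[(group, cond)] = grand_average(
                    [all_measures[i][cond] for i in ids if i in inc])
        return CDAStudyResults(model=self, per_participant=pp,
                               grand_averages=ga, **stats)


def _require_complete(pp: pd.DataFrame) -> None:
    for col in [f"cda_{c}" for c in CONDITIONS] + [f"acc_{c}" for c in CONDITIONS]:
        if col not in pp.columns:
            raise ValueError(f"per-participant records missing column {col!r}")
        bad = pp.loc[pp[col].isna(), "participant"].tolist()
        if bad:
            raise ValueError(f"participant(s) {bad} missing condition measure {col!r}")


def _guarded(test_name: str, effect: str, fn, *args, **kwargs) -> st.StatResult:
    """Run one planned test; degrade degenerate inputs to a missing result.

    Zero-variance cells (possible in tiny simulations) make individual t-tests
    undefined; the study report records them as NaN with the reason instead of
    aborting the whole analysis.
    """
    try:
        return fn(*args, **kwargs)
    except ValueError as exc:
        return st.StatResult(test=test_name, effect=effect, statistic=np.nan,
                             df=(np.nan,), p=np.nan, effect_size=np.nan,
                             effect_size_type=None, notes={"error": str(exc)})


def compute_study_stats(per_participant: pd.DataFrame,
                        d_convention: str = "dz") -> dict:
    """Group-level tables and tests from per-participant records.

    Operates only on rows with ``included == True`` (all rows if the column
    is absent), so a report regenerated from persisted records is
    bit-identical to the one computed at fit time.
    """
    pp = per_participant
    if "included" in pp.columns:
        pp = pp[pp["included"]]
    _require_complete(pp)
    groups = sorted(pp["group"].unique())
    if len(groups) < 2:
        raise ValueError("fewer than 2 groups with included participants "
                         "(participant exclusion removed a whole group)")
    for g in groups:
        if (pp["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 included participants")
    grp = pp["group"].to_numpy()

    # ---- Table 1: group x condition means (SD)
    t1_rows = []
    for g in groups:
        sub = pp[pp["group"] == g]
        for cond in CONDITIONS:
            t1_rows.append({
                "group": g, "condition": cond,
                "accuracy_mean": sub[f"acc_{cond}"].mean(),
                "accuracy_sd": sub[f"acc_{cond}"].std(ddof=1),
                "cda_mean": sub[f"cda_{cond}"].mean(),
                "cda_sd": sub[f"cda_{cond}"].std(ddof=1),
                "diff_mean": sub[f"diff_{cond}"].mean() if cond != "non_dis" else np.nan,
                "diff_sd": sub[f"diff_{cond}"].std(ddof=1) if cond != "non_dis" else np.nan,
            })
    table1 = pd.DataFrame(t1_rows)

    # ---- omnibus ANOVAs and ANCOVA
    acc_wide = pp[[f"acc_{c}" for c in CONDITIONS]]
    cda_wide = pp[[f"cda_{c}" for c in CONDITIONS]]
    omnibus = {
        "accuracy": st.rm_anova_mixed(acc_wide, grp),
        "cda": st.rm_anova_mixed(cda_wide, grp),
        "cda_ancova": st.ancova_mixed(cda_wide, grp, pp["k"].to_numpy()),
    }
    heog_cols = [f"heograte_{c}_{s}" for c in CONDITIONS for s in CUE_SIDES]
    if all(c in pp.columns for c in heog_cols) and not pp[heog_cols].isna().any().any():
        omnibus["rejection_heog"] = st.rm_anova_two_within(
            pp[heog_cols], grp, ("condition", "cue_side"), (len(CONDITIONS), 2))

    # ---- Table 2: planned paired comparisons of CDA per group (+ accuracy)
    t2_rows = []
    paired = {}
    for measure, prefix in (("cda", "cda"), ("accuracy", "acc")):
        for g in groups:
            sub = pp[pp["group"] == g]
            for c1, c2 in _PAIRS:
                r = _guarded("paired_t", f"{c1} vs {c2}", st.paired_t,
                             sub[f"{prefix}_{c1}"], sub[f"{prefix}_{c2}"],
                             d_convention=d_convention, compute_bf=True)
                paired[(measure, g, c1, c2)] = r
                t2_rows.append({"measure": measure, "group": g,
                                "pair": f"{c1} vs {c2}", "df": r.df[0],
                                "t": r.statistic, "p": r.p, "d": r.effect_size,
                                "bf10": r.bf10})
    table2 = pd.DataFrame(t2_rows)

    # ---- between-group comparisons
    g1, g2 = groups[0], groups[-1]
    a, b = pp[pp["group"] == g1], pp[pp["group"] == g2]
    group_tests = {}
    for label, col in (
            [("bdi", "bdi"), ("dass_a", "dass_a"), ("k", "k"), ("d_prime", "d_prime")]
            + [(f"acc_{c}", f"acc_{c}") for c in CONDITIONS]
            + [(f"cda_{c}", f"cda_{c}") for c in CONDITIONS]
            + [(f"diff_{d}", f"diff_{d}") for d in _DISTRACTORS]):
        r = _guarded("independent_t", label, st.independent_t,
                     a[col], b[col], compute_bf=True)
        r.effect = f"{label}: {g1} vs {g2}"
        group_tests[label] = r

    # ---- correlations over the whole included sample
    corr_pairs = ([("bdi", "dass_a"), ("k", "bdi"), ("k", "dass_a")]
                  + [(x, f"diff_{d}") for d in _DISTRACTORS for x in ("k", "bdi", "dass_a")])
    corr_rows = []
    for x, y in corr_pairs:
        r = _guarded("pearson_r", f"{x}~{y}", st.pearson_r, pp[x], pp[y])
        corr_rows.append({"x": x, "y": y, "r": r.statistic, "df": r.df[0], "p": r.p})
    correlations = pd.DataFrame(corr_rows)

    return {"table1": table1, "table2": table2, "omnibus": omnibus,
            "paired_tests": paired, "group_tests": group_tests,
            "correlations": correlations}


@dataclass
class CDAStudyResults:
    """Fitted study results.

    Attributes
    ----------
    per_participant : DataFrame
        One row per participant with all derived measures and the
        ``included`` flag; the sole source of every group-level table.
    table1, table2 : DataFrame
        Group x condition descriptives and planned paired comparisons.
    omnibus : dict
        Mixed ANOVA (accuracy, CDA), rm-ANCOVA with capacity covariate, and
        the condition x hemifield x group rejection-rate ANOVA.
    """

    model: CDAStudy | None
    per_participant: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    omnibus: dict
    paired_tests: dict
    group_tests: dict
    correlations: pd.DataFrame
    grand_averages: dict = field(default_factory=dict)

    @property
    def included(self) -> list[str]:
        return self.per_participant.loc[self.per_participant["included"], "participant"].tolist()

    @property
    def excluded(self) -> list[str]:
        return self.per_participant.loc[~self.per_participant["included"], "participant"].tolist()

    def summary(self) -> str:
        """Human-readable report in the reporting style of ERP studies."""
        pp = self.per_participant
        lines = ["CDA study results", "=" * 60]
        lines.append(f"Participants: {len(pp)} total, {len(self.included)} included, "
                     f"{len(self.excluded)} excluded (rejection rate criterion)")
        lines.append("")
        lines.append("Table 1 - mean (SD) per group x condition")
        for _, r in self.table1.iterrows():
            diff = ("  diff " + f"{r['diff_mean']:.2f} ({r['diff_sd']:.2f})"
                    if np.isfinite(r["diff_mean"]) else "")
            lines.append(f"  {r['group']:>9} {r['condition']:<12} "
                         f"acc {100 * r['accuracy_mean']:.2f}% ({r['accuracy_sd']:.2f})  "
                         f"CDA {r['cda_mean']:.2f} ({r['cda_sd']:.2f}) uV{diff}")
        lines.append("")
        lines.append("Omnibus tests (CDA amplitude)")
        for eff in ("condition", "group", "condition*group"):
            lines.append("  " + str(self.omnibus["cda"][eff]))
        lines.append("  ANCOVA (capacity covariate): "
                     + str(self.omnibus["cda_ancova"]["condition*group"]))
        lines.append("")
        lines.append("Planned paired comparisons (CDA)")
        for _, r in self.table2[self.table2["measure"] == "cda"].iterrows():
            lines.append(f"  {r['group']:>9} {r['pair']:<28} t({r['df']:g}) = "
                         f"{r['t']:.3f}, p = {r['p']:.3f}, d = {r['d']:.3f}, "
                         f"BF10 = {r['bf10']:.3f}")
        lines.append("")
        lines.append("Group comparisons")
        for key in ("k", "d_prime", "diff_fearful_dis", "diff_sad_dis"):
            lines.append("  " + str(self.group_tests[key]))
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Persist per-participant records and report tables as CSV/text."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_participant.to_csv(out / "per_participant.csv", index=False)
        self.table1.to_csv(out / "table1.csv", index=False)
        self.table2.to_csv(out / "table2.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        rows = []
        for label, r in self.group_tests.items():
            rows.append({"test": label, "t": r.statistic, "df": r.df[0],
                         "p": r.p, "d": r.effect_size, "bf10": r.bf10})
        pd.DataFrame(rows).to_csv(out / "group_tests.csv", index=False)
        (out / "report.txt").write_text(self.summary() + "\n", encoding="utf-8")
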
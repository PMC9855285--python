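"""Study orchestration: configuration, seeding, simulation, persistence, report.

``StudyConfig`` bundles every stage's parameters with a master seed.  The
master seed fans out deterministically to per-participant, per-stage child
seeds through :func:`child_rng` (a ``numpy.random.SeedSequence`` keyed on the
master seed, a stage tag and the participant index), so any subset of the
simulation can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .artifacts import RejectionPolicy
from .containers import CONDITIONS
from .lateralized import AnalysisWindows, Montage
from .model import CDAStudy, CDAStudyResults, ParticipantData, compute_study_stats
from .preprocess import PreprocConfig, design_lowpass_fir
from .simulate import (EEGSimConfig, GroupParams, TaskConfig, calibrate_noise_sd,
                       inject_artifacts, make_cohort, simulate_behavior,
                       simulate_epochs, simulate_trial_table, simulate_vwm_task)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "child_rng", "simulate_study", "run_study", "make_report"]


@dataclass
class StudyConfig:
    """Complete configuration of a simulated study run.

    ``noise_wm_sd`` sets the target SD (µV) of the single-trial
    contralateral-minus-ipsilateral window-mean estimate; the per-sample
    noise SD is calibrated from it and the analysis filter.  Set it to None
    to use ``eeg.noise_sd`` directly.
    """

    n_per_group: int = 18
    group_params: dict[str, GroupParams] | None = None
    task: TaskConfig = field(default_factory=TaskConfig)
    eeg: EEGSimConfig = field(default_factory=lambda: EEGSimConfig(
        saccade_rate=0.05, blast_rate=0.02))
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    rejection: RejectionPolicy = field(default_factory=RejectionPolicy)
    montage: Montage = field(default_factory=Montage)
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    noise_wm_sd: float | None = 2.0
    filtering_guess_rate: float = 0.5
    filtering_lapse: float = 0.10
    vwm_guess_rate: float = 0.5
    vwm_lapse: float = 0.0
    master_seed: int = 0
    output_dir: str | None = None

    def resolved_eeg(self) -> EEGSimConfig:
        """EEG config with the per-sample noise SD calibrated if requested."""
        if self.noise_wm_sd is None:
            return self.eeg
        kernel = design_lowpass_fir(self.preproc.lowpass_hz, self.eeg.sampling_rate,
                                    self.preproc.transition_hz)
        sd = calibrate_noise_sd(
            self.noise_wm_sd, n_pairs=len(self.montage.pairs), times=self.eeg.times,
            window=self.windows.cda, baseline=self.preproc.baseline_window,
            kernel=kernel)
        return dataclasses.replace(self.eeg, noise_sd=sd)

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StudyConfig":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        d = json.loads(text)

        def tup(x):
            return tuple(tup(v) if isinstance(v, list) else v for v in x)

        def build(klass, sub):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in sub:
                    continue
                v = sub[f.name]
                kwargs[f.name] = tup(v) if isinstance(v, list) else v
            return klass(**kwargs)

        gp = d.get("group_params")
        if gp is not None:
            gp = {g: build(GroupParams, p) for g, p in gp.items()}
        return cls(
            n_per_group=d.get("n_per_group", 18),
            group_params=gp,
            task=build(TaskConfig, d.get("task", {})),
            eeg=build(EEGSimConfig, d.get("eeg", {})),
            preproc=build(PreprocConfig, d.get("preproc", {})),
            rejection=build(RejectionPolicy, d.get("rejection", {})),
            montage=build(Montage, d.get("montage", {})),
            windows=build(AnalysisWindows, d.get("windows", {})),
            noise_wm_sd=d.get("noise_wm_sd", 2.0),
            filtering_guess_rate=d.get("filtering_guess_rate", 0.5),
            filtering_lapse=d.get("filtering_lapse", 0.10),
            vwm_guess_rate=d.get("vwm_guess_rate", 0.5),
            vwm_lapse=d.get("vwm_lapse", 0.0),
            master_seed=d.get("master_seed", 0),
            output_dir=d.get("output_dir"),
        )


def child_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage, per-participant random generator.

    The stage tag is hashed (CRC-32) into the ``SeedSequence`` entropy, so
    adding stages never shifts the streams of existing ones.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, key, index]))


def _child_seed(master_seed: int, stage: str, index: int = 0) -> int:
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, key, index]).generate_state(1)[0] % (2 ** 31))


def simulate_study(config: StudyConfig) -> CDAStudy:
    """Generate cohort, trial tables, behaviour and EEG for a whole study."""
    ms = config.master_seed
    cohort = make_cohort(config.n_per_group, config.group_params,
                         seed=_child_seed(ms, "cohort"))
    eeg = config.resolved_eeg()
    participants = []
    for i, rec in enumerate(cohort.participants):
        table = simulate_trial_table(config.task, seed=_child_seed(ms, "table", i))
        # at target load 2 a capacity above the load behaves as ceiling storage
        table = simulate_behavior(min(rec.true_k, config.task.set_size_targets),
                                  config.task.set_size_targets,
                                  config.filtering_guess_rate, config.filtering_lapse,
                                  table, seed=_child_seed(ms, "filter-beh", i))
        epochs = simulate_epochs(table, rec, eeg, seed=_child_seed(ms, "eeg", i))
        truth = None
        if eeg.saccade_rate > 0 or eeg.blast_rate > 0:
            epochs, truth = inject_artifacts(epochs, eeg,
                                             seed=_child_seed(ms, "artifacts", i))
        vwm = simulate_vwm_task(rec.true_k, config.task.vwm_task_trials,
                                config.task.vwm_task_set_size,
                                config.vwm_guess_rate, config.vwm_lapse,
                                seed=_child_seed(ms, "vwm", i))
        participants.append(ParticipantData(record=rec, epochs=epochs,
                                            trial_table=table, vwm_table=vwm,
                                            artifact_truth=truth))
        logger.debug("simulated participant %s (%d trials)", rec.id, len(table))
    return CDAStudy(participants, preproc=config.preproc,
                    rejection=config.rejection, montage=config.montage,
                    windows=config.windows)


def run_study(config: StudyConfig) -> CDAStudyResults:
    """Simulate, fit and (optionally) persist a full study.

    With ``config.output_dir`` set, writes the cohort, per-participant trial
    tables, per-participant measures and the report tables.
    """
    study = CDAStudy.from_simulation(config)
    results = study.fit()
    if config.output_dir:
        from .io import write_cohort, write_trial_table
        from .simulate import CohortSpec

        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        cohort = CohortSpec([p.record for p in study.participants],
                            seed=_child_seed(config.master_seed, "cohort"))
        write_cohort(cohort, out / "cohort.json")
        trials_dir = out / "trials"
        trials_dir.mkdir(exist_ok=True)
        for p in study.participants:
            write_trial_table(p.trial_table, trials_dir / f"{p.record.id}.tsv")
        results.save(out)
        logger.info("study written to %s", out)
    return results


def single_participant_cda(amplitude: float = -0.85, n_trials: int = 200,
                           noise_wm_sd: float = 2.0, seed: int = 0,
                           condition: str = "fearful_dis",
                           preproc: PreprocConfig = PreprocConfig(),
                           montage: Montage = Montage(),
                           windows: AnalysisWindows = AnalysisWindows()) -> float:
    """Injection-recovery probe: one participant's pipeline CDA estimate.

    Simulates ``n_trials`` artifact-free trials of one condition with a
    ground-truth contra-minus-ipsi window mean of ``amplitude`` µV and
    single-trial window-mean-level noise SD ``noise_wm_sd`` µV, runs the full
    preprocessing + lateralized-averaging chain, and returns the measured CDA
    amplitude.  Unbiased up to Monte-Carlo error: the estimate SD is
    ``noise_wm_sd / sqrt(n_trials)``.
    """
    from .lateralized import measure_condition
    from .preprocess import preprocess
    from .simulate import ParticipantRecord

    task = TaskConfig(n_trials_per_condition=n_trials, conditions=(condition,),
                      n_blocks=1)
    rng_seeds = np.random.SeedSequence([int(seed)]).generate_state(2) % (2 ** 31)
    table = simulate_trial_table(task, seed=int(rng_seeds[0]))
    kernel = design_lowpass_fir(preproc.lowpass_hz, 1000.0, preproc.transition_hz)
    eeg = EEGSimConfig(noise_sd=0.0)
    eeg = dataclasses.replace(eeg, noise_sd=calibrate_noise_sd(
        noise_wm_sd, n_pairs=len(montage.pairs), times=eeg.times,
        window=windows.cda, baseline=preproc.baseline_window, kernel=kernel))
    rec = ParticipantRecord(id="probe", group="control", bdi=0.0, dass_a=0.0,
                            true_k=3.0, ground_truth_cda={c: amplitude for c in CONDITIONS})
    epochs = simulate_epochs(table, rec, eeg, seed=int(rng_seeds[1]))
    pre = preprocess(epochs, preproc)
    return measure_condition(pre, table, montage, windows, condition).cda_amplitude


def make_report(per_participant: pd.DataFrame | str | Path,
                out_dir: str | Path | None = None,
                d_convention: str = "dz") -> dict:
    """Regenerate all group-level tables from persisted per-participant records.

    Returns the same dict of tables/tests that :meth:`CDAStudy.fit` embeds in
    its results; regeneration from saved intermediates is exact because every
    table derives from the records alone.
    """
    if not isinstance(per_participant, pd.DataFrame):
        per_participant = pd.read_csv(per_participant)
    report = compute_study_stats(per_participant, d_convention=d_convention)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["table1"].to_csv(out / "table1.csv", index=False)
        report["table2"].to_csv(out / "table2.csv", index=False)
        report["correlations"].to_csv(out / "correlations.csv", index=False)
    return report
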
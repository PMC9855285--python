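"""File formats: BrainVision core triples, TSV trial tables, JSON cohorts, HDF5 epochs.

BrainVision files are written directly (multiplexed binary, CRLF-terminated
INI headers, IEEE float32 in µV, 1-based marker positions) and read back via
MNE's BrainVision reader, after a light header validation that turns malformed
files into explicit errors.  Marker positions are 0-based sample indices in
this API and converted at the file boundary.
"""

from __future__ import annotations

import configparser
import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet, validate_trial_table
from .simulate import CohortSpec, ParticipantRecord

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "epochs_to_brainvision",
    "brainvision_to_epochs",
    "write_trial_table",
    "read_trial_table",
    "write_cohort",
    "read_cohort",
    "write_epochs_h5",
    "read_epochs_h5",
]

_CRLF = "\r\n"


def write_brainvision(data: np.ndarray, channel_names: Sequence[str], sfreq: float,
                      markers: Sequence[int], out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write a continuous recording as a BrainVision .vhdr/.vmrk/.eeg triple.

    ``data`` is (n_channels, n_samples) in µV; ``markers`` are 0-based sample
    indices written as ``Stimulus,S  1`` markers (1-based in the file, per the
    format).  Returns the three paths.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[0] != len(channel_names):
        raise ValueError("data must be (n_channels, n_samples) matching channel_names")
    if len(set(channel_names)) != len(channel_names):
        raise ValueError("channel names must be unique")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    n_samp = data.shape[1]
    for m in markers:
        if not 0 <= m < n_samp:
            raise ValueError(f"marker position {m} outside the recording")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stem = prefix.name
    vhdr, vmrk, eeg = (prefix.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    header = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(channel_names)}",
        f"SamplingInterval={1e6 / sfreq:.6g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ] + [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(channel_names)]
    vhdr.write_text(_CRLF.join(header) + _CRLF, encoding="utf-8")

    marker_lines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ] + [f"Mk{i + 2}=Stimulus,S  1,{int(m) + 1},1,0" for i, m in enumerate(markers)]
    vmrk.write_text(_CRLF.join(marker_lines) + _CRLF, encoding="utf-8")

    data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    return vhdr, vmrk, eeg


_KNOWN_FORMATS = {"IEEE_FLOAT_32": np.dtype("<f4"), "INT_16": np.dtype("<i2")}


def _validate_vhdr(vhdr: Path) -> None:
    """Light structural validation producing explicit errors before MNE parses."""
    text = vhdr.read_text(encoding="utf-8", errors="replace")
    cp = configparser.ConfigParser(interpolation=None, strict=False)
    cp.optionxform = str  # keep key case
    try:
        cp.read_string("\n".join(line for line in text.splitlines()
                                 if not line.startswith(("Brain", ";"))))
    except configparser.Error as exc:
        raise ValueError(f"malformed BrainVision header {vhdr.name}: {exc}") from exc
    if "Common Infos" not in cp:
        raise ValueError(f"malformed BrainVision header {vhdr.name}: missing [Common Infos] section")
    common = cp["Common Infos"]
    for key in ("DataFile", "NumberOfChannels", "SamplingInterval"):
        if key not in common:
            raise ValueError(f"malformed BrainVision header {vhdr.name}: missing {key}")
    fmt = cp.get("Binary Infos", "BinaryFormat", fallback="IEEE_FLOAT_32")
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unknown binary format {fmt!r} in {vhdr.name}")
    eeg = vhdr.parent / common["DataFile"]
    if not eeg.exists():
        raise ValueError(f"header references missing data file {eeg.name}")
    n_ch = int(common["NumberOfChannels"])
    size = eeg.stat().st_size
    itemsize = _KNOWN_FORMATS[fmt].itemsize
    if size % (n_ch * itemsize) != 0:
        raise ValueError(
            f"data file size {size} is not a whole number of {n_ch}-channel samples")


def read_brainvision(header_path: str | Path
                     ) -> tuple[np.ndarray, list[str], float, list[int]]:
    """Read a BrainVision triple: (data µV (n_ch, n_samp), names, sfreq, markers).

    Marker positions are returned as 0-based stimulus-onset sample indices.
    Parsing is delegated to MNE after structural validation.
    """
    import mne

    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(vhdr)
    _validate_vhdr(vhdr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
        except Exception as exc:
            raise ValueError(f"failed to read BrainVision file {vhdr.name}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> µV
    sfreq = float(raw.info["sfreq"])
    markers = [int(round(a["onset"] * sfreq)) for a in raw.annotations
               if "Stimulus" in a["description"]]
    return data, list(raw.ch_names), sfreq, markers


def epochs_to_brainvision(epochs: EpochSet, out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Export an EpochSet by concatenating trials, one stimulus marker per onset."""
    n_tr, n_ch, n_t = epochs.data.shape
    cont = epochs.data.transpose(1, 0, 2).reshape(n_ch, n_tr * n_t)
    zero = epochs.time_zero_index
    markers = [i * n_t + zero for i in range(n_tr)]
    return write_brainvision(cont, epochs.channel_names, epochs.sfreq, markers, out_prefix)


def brainvision_to_epochs(header_path: str | Path,
                          epoch_window: tuple[float, float] = (-200.0, 1100.0)) -> EpochSet:
    """Re-epoch an exported recording around its stimulus markers."""
    from .preprocess import extract_epochs

    data, names, sfreq, markers = read_brainvision(header_path)
    return extract_epochs(data, names, sfreq, markers, epoch_window)


# ---------------------------------------------------------------------------
# trial tables (TSV)

def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_trial_table(table)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"trial table file {path.name} is empty")
    table = pd.read_csv(path, sep="\t")
    if len(table) == 0:
        raise ValueError(f"trial table file {path.name} has a header but no rows")
    for col in ("change_present", "response_change", "correct",
                "rejected_heog", "rejected_amp"):
        if col in table.columns:
            table[col] = table[col].astype(bool)
    validate_trial_table(table)
    return table


# ---------------------------------------------------------------------------
# cohorts (JSON)

def write_cohort(cohort: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    payload = {"seed": cohort.seed,
               "participants": [asdict(p) for p in cohort.participants]}
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def read_cohort(path: str | Path) -> CohortSpec:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    participants = [ParticipantRecord(**p) for p in payload["participants"]]
    return CohortSpec(participants=participants, seed=int(payload["seed"]))


# ---------------------------------------------------------------------------
# epochs (HDF5)

def write_epochs_h5(epochs: EpochSet, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["tmin"] = epochs.tmin
        f.attrs["units"] = "uV"
    return path


def read_epochs_h5(path: str | Path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(data=np.asarray(f["data"], float),
                        channel_names=[str(c) for c in f.attrs["channel_names"]],
                        sfreq=float(f.attrs["sfreq"]), tmin=float(f.attrs["tmin"]))
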
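"""File formats: BDF/EDF reading, the package HDF5 container, TSV tables.

Continuous recordings can be read from BioSemi BDF or EDF files (parsed by
mne) or from the package's HDF5 container; epoched data live in the HDF5
container with a JSON metadata block.  Event and onset tables are
tab-separated text.  A minimal 24-bit BDF writer is included so synthetic
recordings can be emitted in the acquisition system's native format and
round-tripped through an independent reader.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .preprocessing import EpochedDataset


@dataclass
class Recording:
    """Continuous multichannel recording in microvolt."""

    data: np.ndarray  # channels x samples
    fs: float
    ch_names: list[str]
    is_eeg: np.ndarray  # bool per channel (False for EOG/aux)


class RecordingParseError(RuntimeError):
    """Malformed recording file; the message names the offending field."""


# ---------------------------------------------------------------- HDF5 container

def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f["data"].attrs["fs"] = rec.fs
        f["data"].attrs["ch_names"] = json.dumps(list(rec.ch_names))
        f["data"].attrs["is_eeg"] = json.dumps([bool(b) for b in rec.is_eeg])


def _read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise RecordingParseError("container is missing the 'data' dataset")
        d = f["data"]
        for attr in ("fs", "ch_names", "is_eeg"):
            if attr not in d.attrs:
                raise RecordingParseError(f"container is missing the {attr!r} attribute")
        return Recording(
            data=d[()],
            fs=float(d.attrs["fs"]),
            ch_names=json.loads(d.attrs["ch_names"]),
            is_eeg=np.asarray(json.loads(d.attrs["is_eeg"]), bool),
        )


def write_epochs(path, epochs: EpochedDataset) -> None:
    """Store an epoch set with a JSON metadata block."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("event_times", data=epochs.event_times)
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.attrs["meta"] = json.dumps(
            {"fs": epochs.fs, "condition": epochs.condition,
             "participant": epochs.participant,
             "ch_names": epochs.ch_names}
        )


def read_epochs(path) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        return EpochedDataset(
            data=f["data"][()], times=f["times"][()], fs=meta["fs"],
            condition=meta["condition"], participant=meta["participant"],
            event_times=f["event_times"][()], trial_index=f["trial_index"][()],
            ch_names=meta["ch_names"],
        )


# ------------------------------------------------------------------- BDF (24-bit)

_BDF_DIG_MAX = 8388607
_BDF_PHYS_MAX = 32768.0  # uV; gain ~3.9 nV per digital unit


def write_bdf(path, rec: Recording) -> None:
    """Write a continuous recording as a BioSemi 24-bit BDF file.

    One-second data records; the recording is truncated to whole records.
    Physical units are microvolt with a fixed +/-32768 uV physical range.
    """
    n_ch, n_samp = rec.data.shape
    spr = int(round(rec.fs))  # samples per 1-s record
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-s data record")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    with open(path, "wb") as f:
        f.write(b"\xffBIOSEMI" + pad("", 80) + pad("", 80))
        f.write(pad("01.01.00", 8) + pad("00.00.00", 8))
        f.write(pad(str(256 * (n_ch + 1)), 8))
        f.write(pad("24BIT", 44))
        f.write(pad(str(n_rec), 8) + pad("1", 8) + pad(str(n_ch), 4))
        for name in rec.ch_names:
            f.write(pad(name, 16))
        for eeg in rec.is_eeg:
            f.write(pad("Active Electrode" if eeg else "EOG electrode", 80))
        f.write(pad("uV", 8) * n_ch)
        f.write(pad(str(-_BDF_PHYS_MAX), 8) * n_ch)
        f.write(pad(str(_BDF_PHYS_MAX), 8) * n_ch)
        f.write(pad(str(-_BDF_DIG_MAX - 1), 8) * n_ch)
        f.write(pad(str(_BDF_DIG_MAX), 8) * n_ch)
        f.write(pad("", 80) * n_ch)  # prefiltering
        f.write(pad(str(spr), 8) * n_ch)
        f.write(pad("", 32) * n_ch)

        gain = _BDF_PHYS_MAX / (_BDF_DIG_MAX + 1)
        digital = np.clip(
            np.round(rec.data[:, : n_rec * spr] / gain), -_BDF_DIG_MAX - 1, _BDF_DIG_MAX
        ).astype(np.int32)
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            le32 = chunk.astype("<i4").tobytes()  # keep low 3 of 4 bytes
            arr = np.frombuffer(le32, dtype=np.uint8).reshape(n_ch * spr, 4)
            f.write(arr[:, :3].tobytes())


def _read_recording_mne(path) -> Recording:
    import mne

    path = str(path)
    try:
        if path.lower().endswith(".bdf"):
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # surface mne's header complaint
        raise RecordingParseError(f"cannot parse {path}: {err}") from err
    data = raw.get_data() * 1e6  # volt -> microvolt
    kinds = raw.get_channel_types()
    is_eeg = np.array([k == "eeg" for k in kinds])
    # BioSemi montages carry EOG in the channel name/type; flag non-EEG channels
    for i, name in enumerate(raw.ch_names):
        if "EOG" in name.upper():
            is_eeg[i] = False
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     ch_names=list(raw.ch_names), is_eeg=is_eeg)


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read a continuous recording; format from the extension unless given.

    Supported: ``"bdf"``, ``"edf"`` (via mne) and ``"h5"`` (the package
    container).
    """
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt in ("h5", "hdf5"):
        return _read_recording_h5(path)
    if fmt in ("bdf", "edf"):
        return _read_recording_mne(path)
    raise ValueError(f"unknown recording format {fmt!r}")


# ------------------------------------------------------------------------ tables

def write_event_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_event_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_onset_table(path, onsets: pd.DataFrame) -> None:
    onsets.to_csv(path, sep="\t", index=False)


def read_onset_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scr_trace(path, samples: np.ndarray, fs: float) -> None:
    """Two-column TSV: time_s, conductance_uS."""
    t = np.arange(len(samples)) / fs
    pd.DataFrame({"time_s": t, "conductance_uS": samples}).to_csv(path, sep="\t", index=False)


def read_scr_trace(path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return df["conductance_uS"].to_numpy(), float(round(fs, 6))
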
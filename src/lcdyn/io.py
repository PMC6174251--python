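"""File interchange: HDF5 matrices, TSV tables, .sfp positions, BrainVision.

EEG records are read through mne (EDF and BrainVision dialects). BrainVision
writing is implemented here directly — the triplet is a text header (.vhdr),
a text marker file (.vmrk) and an IEEE float32 multiplexed binary (.eeg) —
and round-trips through mne's reader.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np

from .data import EEGData, ERP, Leadfield, SourceActivity


# ---------------------------------------------------------------------------
# HDF5


def write_leadfield(lf: Leadfield, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("leadfield", data=lf.gain)
        if lf.channel_names is not None:
            f.create_dataset(
                "channel_names", data=np.array(lf.channel_names, dtype="S")
            )
        if lf.source_positions is not None:
            f.create_dataset("source_positions", data=lf.source_positions)


def read_leadfield(path) -> Leadfield:
    with h5py.File(path, "r") as f:
        gain = f["leadfield"][()]
        names = (
            [n.decode() for n in f["channel_names"][()]]
            if "channel_names" in f
            else None
        )
        pos = f["source_positions"][()] if "source_positions" in f else None
    return Leadfield(gain, names, pos)


def write_source_activity(src: SourceActivity, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("currents", data=src.currents)
        d.attrs["fs"] = src.fs
        d.attrs["time_zero"] = src.time_zero
        d.attrs["kind"] = src.kind


def read_source_activity(path) -> SourceActivity:
    with h5py.File(path, "r") as f:
        d = f["currents"]
        return SourceActivity(
            d[()], float(d.attrs["fs"]), int(d.attrs["time_zero"]), str(d.attrs["kind"])
        )


def write_erp(erp: ERP, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("erp", data=erp.mean)
        d.attrs["fs"] = erp.fs
        d.attrs["n_trials"] = erp.n_trials
        d.attrs["window_ms"] = erp.window_ms
        d.attrs["condition"] = erp.condition
        if erp.channel_names is not None:
            f.create_dataset("channel_names", data=np.array(erp.channel_names, "S"))


def read_erp(path) -> ERP:
    with h5py.File(path, "r") as f:
        d = f["erp"]
        names = (
            [n.decode() for n in f["channel_names"][()]]
            if "channel_names" in f
            else None
        )
        return ERP(
            d[()],
            int(d.attrs["n_trials"]),
            float(d.attrs["fs"]),
            tuple(d.attrs["window_ms"]),
            names,
            str(d.attrs["condition"]),
        )


# ---------------------------------------------------------------------------
# electrode positions (.sfp: name x y z per line)


def write_sfp(names, positions, path) -> None:
    with open(path, "w") as f:
        for name, (x, y, z) in zip(names, np.asarray(positions, dtype=float)):
            f.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_sfp(path) -> tuple[list[str], np.ndarray]:
    names, rows = [], []
    with open(path) as f:
        for line in f:
            parts = line.split()
            if len(parts) != 4:
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return names, np.asarray(rows)


# ---------------------------------------------------------------------------
# BrainVision triplet


def write_brainvision(rec: EEGData, basename) -> Path:
    """Write ``<basename>.vhdr/.vmrk/.eeg`` (multiplexed IEEE float32, µV)."""
    base = Path(basename)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = rec.n_channels

    data = np.asarray(rec.samples, dtype="<f4").T.reshape(-1)  # multiplexed
    data.tofile(eeg)

    with open(vhdr, "w") as f:
        f.write("Brain Vision Data Exchange Header File Version 1.0\n\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={n_ch}\n")
        f.write(f"SamplingInterval={1e6 / rec.fs:.6f}\n\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        f.write("[Channel Infos]\n")
        for i, name in enumerate(rec.channel_names, start=1):
            f.write(f"Ch{i}={name},,1,µV\n")

    with open(vmrk, "w") as f:
        f.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={eeg.name}\n\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0\n")
        for k, (idx, label) in enumerate(rec.events, start=2):
            # BrainVision marker positions are 1-based
            f.write(f"Mk{k}=Stimulus,{label},{idx + 1},1,0\n")
    return vhdr


def read_brainvision(vhdr_path) -> EEGData:
    """Read a BrainVision triplet through mne."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("Stimulus/"):
            events.append((int(round(onset * raw.info["sfreq"])), desc.split("/", 1)[1]))
    return EEGData(data, raw.info["sfreq"], raw.ch_names, None, events)


def read_edf(path) -> EEGData:
    """Read an EDF record through mne (channels in µV, stim annotations kept)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    events = [
        (int(round(onset * raw.info["sfreq"])), desc)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGData(data, raw.info["sfreq"], raw.ch_names, None, events)


def read_eeg(path) -> EEGData:
    """Dispatch on extension: .vhdr -> BrainVision, .edf -> EDF."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".vhdr":
        return read_brainvision(path)
    if ext == ".edf":
        return read_edf(path)
    raise ValueError(f"unsupported EEG format: {ext}")
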
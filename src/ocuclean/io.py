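"""File interfaces: HDF5 and delimited-text writers, EDF reader.

HDF5 layout for an :class:`~ocuclean.semisim.EpochTensor`:
``/data`` (channels x time x epochs), ``/labels``, ``/fs``,
``/channel_roles`` plus the optional ``/clean`` and ``/artifact`` blocks
when present.  Delimited text writes one CSV per epoch (rows = channels).
EDF reading goes through :mod:`mne` (optional dependency) and segments the
continuous recording into fixed-duration epochs; annotations are ignored.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .semisim import EpochTensor

__all__ = [
    "write_hdf5",
    "read_hdf5",
    "write_epoch_csvs",
    "read_epoch_csvs",
    "read_edf",
    "write_feature_csv",
    "write_report_text",
]


def write_hdf5(tensor: EpochTensor, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.data)
        f.create_dataset("labels", data=tensor.labels)
        f.create_dataset("fs", data=float(tensor.fs))
        f.create_dataset(
            "channel_roles",
            data=np.array([r.encode("ascii") for r in tensor.channel_roles]),
        )
        if tensor.clean is not None:
            f.create_dataset("clean", data=tensor.clean)
        if tensor.artifact is not None:
            f.create_dataset("artifact", data=tensor.artifact)


def read_hdf5(path: str | Path) -> EpochTensor:
    with h5py.File(path, "r") as f:
        return EpochTensor(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            labels=f["labels"][()],
            channel_roles=[r.decode("ascii") for r in f["channel_roles"][()]],
            clean=f["clean"][()] if "clean" in f else None,
            artifact=f["artifact"][()] if "artifact" in f else None,
        )


def write_epoch_csvs(tensor: EpochTensor, directory: str | Path) -> list[Path]:
    """One delimited-text file per epoch; rows are channels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    width = len(str(tensor.n_epochs - 1))
    for ep in range(tensor.n_epochs):
        p = directory / f"epoch_{ep:0{width}d}.csv"
        np.savetxt(p, tensor.data[:, :, ep], delimiter=",")
        paths.append(p)
    meta = directory / "epochs_meta.csv"
    with open(meta, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fs", tensor.fs])
        w.writerow(["labels", *tensor.labels.tolist()])
        w.writerow(["channel_roles", *tensor.channel_roles])
    paths.append(meta)
    return paths


def read_epoch_csvs(directory: str | Path) -> EpochTensor:
    directory = Path(directory)
    meta = directory / "epochs_meta.csv"
    with open(meta, newline="") as fh:
        rows = {r[0]: r[1:] for r in csv.reader(fh)}
    fs = float(rows["fs"][0])
    labels = np.array([int(v) for v in rows["labels"]], dtype=np.int8)
    roles = list(rows["channel_roles"])
    files = sorted(p for p in directory.glob("epoch_*.csv"))
    data = np.stack(
        [np.loadtxt(p, delimiter=",", ndmin=2) for p in files], axis=2
    )
    return EpochTensor(data=data, fs=fs, labels=labels, channel_roles=roles)


def read_edf(
    path: str | Path,
    epoch_duration: float = 6.0,
    eog_channels: tuple[str, ...] | None = None,
) -> EpochTensor:
    """Read a continuous EDF recording and segment it into epochs.

    Channel roles default to EEG, or EOG for channels whose name appears in
    ``eog_channels`` (or contains "EOG").  Epoch labels are initialized to -1
    (unknown ground truth); annotations are ignored.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install ocuclean[edf])"
        ) from exc

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    n_t = int(round(fs * epoch_duration))
    n_ep = data.shape[1] // n_t
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    epochs = data[:, : n_ep * n_t].reshape(data.shape[0], n_ep, n_t).transpose(0, 2, 1)
    roles = []
    for name in raw.ch_names:
        is_eog = (eog_channels is not None and name in eog_channels) or (
            "EOG" in name.upper()
        )
        roles.append("EOG" if is_eog else "EEG")
    return EpochTensor(
        data=epochs,
        fs=fs,
        labels=np.full(n_ep, -1, dtype=np.int8),
        channel_roles=roles,
    )


def write_feature_csv(path: str | Path, values: np.ndarray, tags) -> None:
    """Feature matrix with a header of tagged column names."""
    header = ",".join(f"{t}_{i}" for i, t in enumerate(tags))
    np.savetxt(path, values, delimiter=",", header=header, comments="")


def write_report_text(path: str | Path, report: dict) -> None:
    """One metric per line, ``key: value``."""
    with open(path, "w") as fh:
        for key, value in report.items():
            fh.write(f"{key}: {value}\n")
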
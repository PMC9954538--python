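"""Reading and writing recordings and epoch sets.

Containers are deliberately plain: an NPZ or HDF5 file with ``data``
(channels x samples for continuous records, trials x channels x timepoints
for epochs), ``channel_names``, ``sampling_rate``, plus ``labels`` for
epochs and one ``marker_times/<name>`` array per marker stream for
continuous records.  EDF input is supported through MNE when it is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .montage import EpochSet
from .synthetic import ContinuousRecord

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_record",
    "load_record",
    "read_edf",
]


def _as_path(path: str | Path) -> Path:
    return Path(path)


def save_epochs(path: str | Path, epochs: EpochSet, metadata: dict | None = None) -> None:
    """Write an EpochSet to ``.npz`` or ``.h5``/``.hdf5`` (by extension)."""
    path = _as_path(path)
    meta = json.dumps(metadata or {})
    if path.suffix == ".npz":
        np.savez(
            path,
            data=epochs.data,
            labels=epochs.labels,
            sampling_rate=epochs.sampling_rate,
            channel_names=np.array(epochs.channel_names, dtype="U32"),
            metadata=np.array(meta),
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=epochs.data)
            fh.create_dataset("labels", data=np.asarray(epochs.labels))
            fh.attrs["sampling_rate"] = epochs.sampling_rate
            fh.create_dataset(
                "channel_names",
                data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
            )
            fh.attrs["metadata"] = meta
    else:
        raise ValueError(f"unsupported epoch container: {path.suffix!r}")


def load_epochs(path: str | Path) -> EpochSet:
    path = _as_path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return EpochSet(
                z["data"], z["labels"], float(z["sampling_rate"]),
                tuple(str(c) for c in z["channel_names"]),
            )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return EpochSet(
                fh["data"][...], fh["labels"][...], float(fh.attrs["sampling_rate"]),
                tuple(c.decode() if isinstance(c, bytes) else str(c)
                      for c in fh["channel_names"][...]),
            )
    raise ValueError(f"unsupported epoch container: {path.suffix!r}")


def save_record(path: str | Path, record: ContinuousRecord) -> None:
    """Write a ContinuousRecord to ``.npz`` or ``.h5``/``.hdf5``."""
    path = _as_path(path)
    if path.suffix == ".npz":
        arrays = {
            "data": record.data,
            "sampling_rate": record.sampling_rate,
            "channel_names": np.array(record.channel_names, dtype="U32"),
        }
        for name, times in record.markers.items():
            arrays[f"marker_times/{name}"] = times
        np.savez(path, **arrays)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=record.data)
            fh.attrs["sampling_rate"] = record.sampling_rate
            fh.create_dataset(
                "channel_names",
                data=np.array(record.channel_names, dtype=h5py.string_dtype()),
            )
            grp = fh.create_group("marker_times")
            for name, times in record.markers.items():
                grp.create_dataset(name, data=times)
    else:
        raise ValueError(f"unsupported record container: {path.suffix!r}")


def load_record(path: str | Path) -> ContinuousRecord:
    path = _as_path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            markers = {
                key.split("/", 1)[1]: z[key]
                for key in z.files if key.startswith("marker_times/")
            }
            return ContinuousRecord(
                z["data"], tuple(str(c) for c in z["channel_names"]),
                float(z["sampling_rate"]), markers,
            )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            markers = {name: fh["marker_times"][name][...]
                       for name in fh.get("marker_times", {})}
            return ContinuousRecord(
                fh["data"][...],
                tuple(c.decode() if isinstance(c, bytes) else str(c)
                      for c in fh["channel_names"][...]),
                float(fh.attrs["sampling_rate"]), markers,
            )
    raise ValueError(f"unsupported record container: {path.suffix!r}")


def read_edf(path: str | Path) -> ContinuousRecord:
    """Read an EDF recording into a ContinuousRecord (requires MNE).

    Annotations become marker streams keyed by annotation description.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    markers: dict[str, list[float]] = {}
    for ann in raw.annotations:
        markers.setdefault(str(ann["description"]), []).append(float(ann["onset"]))
    return ContinuousRecord(
        raw.get_data(),
        tuple(raw.ch_names),
        float(raw.info["sfreq"]),
        {k: np.array(v) for k, v in markers.items()},
    )
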
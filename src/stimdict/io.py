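"""Readers and writers for epoched recordings and recovery results.

Canonical on-disk layout is HDF5: dataset ``/data`` (float64, t × c × e) with
attributes ``fs`` (Hz), ``stim_channels`` (int pair) and ``units``; an
optional ``dim_order`` attribute (a permutation of ``"tce"``) lets any
axis layout be read back into the canonical (t, c, e) order. MATLAB files are
accepted read-only (v7.3 MAT files are HDF5 underneath; older versions go
through scipy.io). Internally all voltages are microvolts; readers convert
from the units attribute, and assume microvolts (with a warning) when it is
absent.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import LEDGER_COLUMNS, EpochedRecording, RecoveryResult

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The container is missing a required array or attribute."""


_UNIT_FACTORS = {"uv": 1.0, "µv": 1.0, "microvolts": 1.0,
                 "mv": 1e3, "millivolts": 1e3, "v": 1e6, "volts": 1e6}


def _unit_factor(units: str | None) -> float:
    if units is None:
        logger.warning("no units attribute; assuming microvolts")
        return 1.0
    factor = _UNIT_FACTORS.get(str(units).strip().lower())
    if factor is None:
        raise FormatError(f"unrecognised units attribute {units!r}")
    return factor


def _canonicalize(data: np.ndarray, dim_order: str) -> np.ndarray:
    dim_order = dim_order.lower()
    if sorted(dim_order) != ["c", "e", "t"]:
        raise FormatError(f"dim_order must be a permutation of 'tce'; got {dim_order!r}")
    return np.transpose(data, [dim_order.index(ax) for ax in "tce"])


def infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".mat":
        return "mat"
    raise FormatError(f"cannot infer container format from suffix {suffix!r}")


def read_recording(path: str | Path, format: str | None = None) -> EpochedRecording:
    """Read an epoched recording from HDF5 or MAT into (t, c, e) microvolts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = format or infer_format(path)
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "mat":
        return _read_mat(path)
    raise FormatError(f"unknown format {format!r}; use 'hdf5' or 'mat'")


def _read_hdf5(path: Path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path}: missing dataset 'data'")
        dset = f["data"]
        if "fs" not in dset.attrs and "fs" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'fs'")
        attrs = dict(f.attrs)
        attrs.update(dset.attrs)
        data = np.asarray(dset, dtype=np.float64)
        fs = float(np.asarray(attrs["fs"]).squeeze())
        if "stim_channels" not in attrs:
            raise FormatError(f"{path}: missing attribute 'stim_channels'")
        stim = tuple(int(s) for s in np.asarray(attrs["stim_channels"]).ravel())
        units = attrs.get("units")
        if isinstance(units, bytes):
            units = units.decode()
        data = _canonicalize(data, str(attrs.get("dim_order", "tce")))
        data = data * _unit_factor(units)
        labels = None
        if "channel_labels" in f:
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["channel_labels"][()]]
        onsets = np.asarray(f["epoch_onsets"]) if "epoch_onsets" in f else None
        return EpochedRecording(data=data, fs=fs, stim_channels=stim,
                                epoch_onsets=onsets, channel_labels=labels)


def _read_mat(path: Path) -> EpochedRecording:
    try:
        from scipy.io import loadmat

        mat = loadmat(path)
    except NotImplementedError:  # v7.3 files are HDF5
        return _read_mat73(path)
    if "data" not in mat:
        raise FormatError(f"{path}: missing variable 'data'")
    for key in ("fs", "stim_channels"):
        if key not in mat:
            raise FormatError(f"{path}: missing variable {key!r}")
    data = np.asarray(mat["data"], dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: 'data' must be 3-D; got shape {data.shape}")
    dim_order = "tce"
    if "dim_order" in mat:
        dim_order = str(np.asarray(mat["dim_order"]).ravel()[0])
    units = None
    if "units" in mat:
        units = str(np.asarray(mat["units"]).ravel()[0])
    data = _canonicalize(data, dim_order) * _unit_factor(units)
    fs = float(np.asarray(mat["fs"]).squeeze())
    stim = tuple(int(s) for s in np.asarray(mat["stim_channels"]).ravel())
    rec = EpochedRecording(data=data, fs=fs, stim_channels=stim)
    if not np.all(np.isfinite(rec.data)):
        raise FormatError(f"{path}: non-finite samples")
    return rec


def _read_mat73(path: Path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path}: missing variable 'data'")
        for key in ("fs", "stim_channels"):
            if key not in f:
                raise FormatError(f"{path}: missing variable {key!r}")
        # MATLAB v7.3 stores arrays transposed (column-major)
        data = np.asarray(f["data"], dtype=np.float64).T
        fs = float(np.asarray(f["fs"]).squeeze())
        stim = tuple(int(s) for s in np.asarray(f["stim_channels"]).ravel())
    return EpochedRecording(data=data, fs=fs, stim_channels=stim)


def write_recording(rec: EpochedRecording, path: str | Path) -> Path:
    """Write a recording in the canonical HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=rec.data.astype(np.float64))
        dset.attrs["fs"] = rec.fs
        dset.attrs["stim_channels"] = np.asarray(rec.stim_channels, dtype=np.int64)
        dset.attrs["units"] = "uV"
        dset.attrs["dim_order"] = "tce"
        if rec.epoch_onsets is not None:
            f.create_dataset("epoch_onsets", data=rec.epoch_onsets)
        if rec.channel_labels is not None:
            f.create_dataset(
                "channel_labels",
                data=np.array([s.encode() for s in rec.channel_labels]),
            )
    return path


def write_result(result: RecoveryResult, path: str | Path) -> Path:
    """Serialize a recovery result (recovered array + subtraction ledger).

    Round-trips bit-exactly: ``read_result(write_result(x))`` reproduces the
    recovered array and ledger.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        rec = result.recovered
        dset = f.create_dataset("recovered", data=rec.data.astype(np.float64))
        dset.attrs["fs"] = rec.fs
        dset.attrs["stim_channels"] = np.asarray(rec.stim_channels, dtype=np.int64)
        dset.attrs["units"] = "uV"
        dset.attrs["dim_order"] = "tce"
        f.attrs["method"] = result.method
        f.attrs["failed"] = bool(result.failed)
        grp = f.create_group("ledger")
        for col in LEDGER_COLUMNS:
            values = result.ledger[col].to_numpy() if len(result.ledger) else np.empty(0)
            grp.create_dataset(col, data=values)
    return path


def read_result(path: str | Path) -> RecoveryResult:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "recovered" not in f:
            raise FormatError(f"{path}: missing dataset 'recovered'")
        dset = f["recovered"]
        rec = EpochedRecording(
            data=np.asarray(dset, dtype=np.float64),
            fs=float(dset.attrs["fs"]),
            stim_channels=tuple(int(s) for s in dset.attrs["stim_channels"]),
        )
        ledger = pd.DataFrame(
            {col: np.asarray(f["ledger"][col]) for col in LEDGER_COLUMNS}
        )
        for col in ("channel", "epoch", "pulse", "start", "stop", "template_id"):
            ledger[col] = ledger[col].astype(np.int64)
        return RecoveryResult(
            recovered=rec, ledger=ledger,
            method=str(f.attrs.get("method", "dictionary")),
            failed=bool(f.attrs.get("failed", False)),
        )


def write_ledger_csv(result: RecoveryResult, path: str | Path) -> Path:
    path = Path(path)
    result.ledger.to_csv(path, index=False)
    return path


def write_dictionary(dictionary, path: str | Path) -> Path:
    """Serialize a template dictionary (templates, labels, outlier scores)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for chan, d in dictionary.channels.items():
            grp = f.create_group(f"channel_{chan}")
            ids = sorted(d.templates)
            grp.create_dataset("template_ids", data=np.asarray(ids, dtype=np.int64))
            grp.create_dataset("templates", data=np.stack([d.templates[i] for i in ids]))
            grp.create_dataset("labels", data=d.labels)
            grp.create_dataset("outlier_scores", data=d.outlier_scores)
    return path


def read_dictionary(path: str | Path):
    from .containers import ChannelDictionary, TemplateDictionary

    channels = {}
    with h5py.File(path, "r") as f:
        for name in f:
            if not name.startswith("channel_"):
                continue
            grp = f[name]
            ids = np.asarray(grp["template_ids"], dtype=np.int64)
            mats = np.asarray(grp["templates"])
            channels[int(name.split("_", 1)[1])] = ChannelDictionary(
                templates={int(i): mats[j] for j, i in enumerate(ids)},
                labels=np.asarray(grp["labels"], dtype=np.int64),
                outlier_scores=np.asarray(grp["outlier_scores"]),
            )
    return TemplateDictionary(channels)
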
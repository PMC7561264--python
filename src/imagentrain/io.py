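"""HDF5 container for trial epochs and JSON helpers.

Schema (one file per dataset):

* ``data``: float array, trials x channels x samples
* ``times``: seconds, epoch-relative, 0 at cue/stimulus onset
* attribute ``sampling_rate`` (Hz)
* group ``trials`` with one column dataset each: subject, block, trial, song,
  condition, rt_seconds (NaN for listening), short
* group ``channels`` with columns name, x, y, z
* optional ``entrained``: ground-truth entrained channel indices (synthetic
  data only)
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .synthgen import TrialEpochs

__all__ = ["write_epochs", "read_epochs", "SchemaError", "dump_json"]

_TRIAL_COLUMNS = ("subject", "block", "trial", "song", "condition", "rt_seconds", "short")
_CHANNEL_COLUMNS = ("name", "x", "y", "z")


class SchemaError(ValueError):
    """The container is missing required datasets or attributes."""


def write_epochs(epochs: TrialEpochs, path) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(epochs.data, dtype=np.float64))
        f.create_dataset("times", data=np.asarray(epochs.times, dtype=np.float64))
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        tg = f.create_group("trials")
        for col in _TRIAL_COLUMNS:
            if col not in epochs.trials.columns:
                if col == "short":
                    vals = np.zeros(len(epochs.trials), dtype=bool)
                else:
                    raise SchemaError(f"trials table lacks column {col!r}")
            else:
                vals = epochs.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                tg.create_dataset(col, data=np.asarray(vals, dtype=object), dtype=str_dt)
            else:
                tg.create_dataset(col, data=vals)
        cg = f.create_group("channels")
        for col in _CHANNEL_COLUMNS:
            vals = epochs.channels[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                cg.create_dataset(col, data=np.asarray(vals, dtype=object), dtype=str_dt)
            else:
                cg.create_dataset(col, data=vals)
        if len(epochs.entrained):
            f.create_dataset("entrained", data=np.asarray(epochs.entrained, dtype=np.int64))


def read_epochs(path) -> TrialEpochs:
    with h5py.File(path, "r") as f:
        missing = [k for k in ("data", "times", "trials", "channels") if k not in f]
        if "sampling_rate" not in f.attrs:
            missing.append("attribute sampling_rate")
        if missing:
            raise SchemaError(f"epochs container missing: {', '.join(missing)}")
        tg = f["trials"]
        missing = [f"trials/{c}" for c in _TRIAL_COLUMNS if c not in tg]
        missing += [f"channels/{c}" for c in _CHANNEL_COLUMNS if c not in f["channels"]]
        if missing:
            raise SchemaError(f"epochs container missing: {', '.join(missing)}")

        def col(group, name):
            arr = group[name][()]
            if arr.dtype.kind in "OS":
                return np.array([v.decode() if isinstance(v, bytes) else v for v in arr])
            return arr

        trials = pd.DataFrame({c: col(tg, c) for c in _TRIAL_COLUMNS})
        channels = pd.DataFrame({c: col(f["channels"], c) for c in _CHANNEL_COLUMNS})
        entrained = f["entrained"][()] if "entrained" in f else np.array([], dtype=int)
        return TrialEpochs(
            data=f["data"][()],
            times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            trials=trials,
            channels=channels,
            entrained=np.asarray(entrained, dtype=int),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
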
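"""Dataset container I/O: HDF5 arrays, CSV event tables, JSON configs.

The HDF5 layout is versioned (`layout_version` root attribute).  Groups:
``/hg/<participant>`` and ``/lfp/<participant>`` hold one epoch set each
(data, times, electrodes, per-trial event columns); ``/events`` and
``/truth/<name>`` hold tables column-wise.  Round trips are lossless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import h5py

from .containers import Dataset, EpochSet, RawRecording

__all__ = [
    "LAYOUT_VERSION",
    "write_dataset",
    "read_dataset",
    "read_events_csv",
    "write_raw_recording",
    "read_raw_recording",
]

LAYOUT_VERSION = "votcortex-dataset-1"
EVENT_COLUMNS = ("participant", "trial", "vot_ms", "response", "rt_ms")
_STR = h5py.string_dtype(encoding="utf-8")


def _write_table(group: h5py.Group, df: pd.DataFrame) -> None:
    group.attrs["columns"] = list(df.columns)
    for col in df.columns:
        vals = df[col].to_numpy()
        if vals.dtype == object or pd.api.types.is_string_dtype(df[col]):
            group.create_dataset(col, data=np.asarray(vals, dtype=object), dtype=_STR)
        else:
            group.create_dataset(col, data=vals)


def _read_table(group: h5py.Group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    data = {}
    for col in cols:
        vals = group[col][()]
        if vals.dtype.kind in ("O", "S"):
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
        data[col] = vals
    return pd.DataFrame(data, columns=cols)


def _write_epochset(group: h5py.Group, es: EpochSet) -> None:
    group.create_dataset("data", data=es.data)
    group.create_dataset("times", data=es.times)
    group.create_dataset("electrodes", data=np.asarray(es.electrodes, dtype=object), dtype=_STR)
    group.attrs["sfreq"] = es.sfreq
    group.attrs["kind"] = es.kind
    _write_table(group.create_group("events"), es.events)


def _read_epochset(group: h5py.Group) -> EpochSet:
    electrodes = [
        e.decode() if isinstance(e, bytes) else e for e in group["electrodes"][()]
    ]
    return EpochSet(
        data=group["data"][()],
        sfreq=float(group.attrs["sfreq"]),
        times=group["times"][()],
        events=_read_table(group["events"]),
        electrodes=electrodes,
        kind=str(group.attrs["kind"]),
    )


def write_dataset(dataset: Dataset, path, events_csv: str | None = None) -> None:
    """Write a Dataset to versioned HDF5 (and optionally the events CSV)."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        hg = f.create_group("hg")
        for pid, es in dataset.hg.items():
            _write_epochset(hg.create_group(pid), es)
        lfp = f.create_group("lfp")
        for pid, es in dataset.lfp.items():
            _write_epochset(lfp.create_group(pid), es)
        if dataset.events is not None:
            _write_table(f.create_group("events"), dataset.events)
        truth = f.create_group("truth")
        for name, df in dataset.truth.items():
            _write_table(truth.create_group(name), df)
    if events_csv is not None and dataset.events is not None:
        dataset.events.to_csv(events_csv, index=False)


def read_dataset(path) -> Dataset:
    """Read a versioned HDF5 dataset; errors name the offending group."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("layout_version")
        if version != LAYOUT_VERSION:
            raise ValueError(
                f"unknown dataset layout version {version!r}; this reader handles "
                f"{LAYOUT_VERSION!r} (re-export the dataset with a matching "
                "votcortex version)"
            )
        if "hg" not in f:
            raise KeyError("dataset is missing required group '/hg'")
        ds = Dataset()
        for pid in f["hg"]:
            ds.hg[pid] = _read_epochset(f["hg"][pid])
        if "lfp" in f:
            for pid in f["lfp"]:
                ds.lfp[pid] = _read_epochset(f["lfp"][pid])
        if "events" in f:
            ds.events = _read_table(f["events"])
        if "truth" in f:
            for name in f["truth"]:
                ds.truth[name] = _read_table(f["truth"][name])
    return ds


def write_raw_recording(raw: RawRecording, path) -> None:
    """Continuous record to HDF5 (data, onsets, masks, sampling rate)."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["sfreq"] = raw.sfreq
        f.create_dataset("data", data=raw.data)
        f.create_dataset("event_onsets", data=raw.event_onsets)
        f.create_dataset(
            "electrodes", data=np.asarray(raw.electrodes, dtype=object), dtype=_STR
        )
        f.create_dataset("bad_channels", data=raw.bad_channels)
        f.create_dataset("bad_segments", data=raw.bad_segments)


def read_raw_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("layout_version")
        if version != LAYOUT_VERSION:
            raise ValueError(
                f"unknown raw layout version {version!r}; expected {LAYOUT_VERSION!r}"
            )
        electrodes = [
            e.decode() if isinstance(e, bytes) else e for e in f["electrodes"][()]
        ]
        return RawRecording(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            event_onsets=f["event_onsets"][()],
            electrodes=electrodes,
            bad_channels=f["bad_channels"][()].astype(bool),
            bad_segments=f["bad_segments"][()].astype(bool),
        )


def read_events_csv(path) -> pd.DataFrame:
    """Load and validate an events CSV.

    Required columns: participant, trial, vot_ms, response, rt_ms.  The
    numeric columns must parse (response and rt_ms may be empty for passive
    trials); the first malformed row aborts the load with its line number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"events CSV missing columns: {missing}")
    out = {"participant": raw["participant"]}
    for col, required in (
        ("trial", True),
        ("vot_ms", True),
        ("response", False),
        ("rt_ms", False),
    ):
        s = raw[col].str.strip()
        empty = s == ""
        if required and empty.any():
            line = int(np.nonzero(empty.to_numpy())[0][0]) + 2
            raise ValueError(f"events CSV line {line}: empty value in column {col!r}")
        num = pd.to_numeric(s.where(~empty, None), errors="coerce")
        bad = num.isna() & ~empty
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise ValueError(
                f"events CSV line {line}: cannot parse {s[bad].iloc[0]!r} in column {col!r}"
            )
        out[col] = num
    df = pd.DataFrame(out)[list(EVENT_COLUMNS)]
    df["trial"] = df["trial"].astype(int)
    return df
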
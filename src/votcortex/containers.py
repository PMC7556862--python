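"""In-memory containers for continuous recordings and trial epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RawRecording", "EpochSet", "Dataset", "EPOCH_WINDOW_MS"]

EPOCH_WINDOW_MS = (-500.0, 1000.0)


@dataclass
class RawRecording:
    """Continuous multichannel voltage (or analytic amplitude) record.

    ``data`` is electrodes x samples.  ``bad_channels`` is a boolean mask per
    electrode; ``bad_segments`` a boolean mask per sample (True = excluded,
    e.g. epileptiform activity).  Event onsets are sample indices of stimulus
    onsets, strictly increasing.
    """

    data: np.ndarray
    sfreq: float
    event_onsets: np.ndarray
    electrodes: list[str] = field(default_factory=list)
    bad_channels: np.ndarray | None = None
    bad_segments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be electrodes x samples")
        n_el, n_s = self.data.shape
        if not self.electrodes:
            self.electrodes = [f"e{i}" for i in range(n_el)]
        if len(self.electrodes) != n_el:
            raise ValueError("electrode names do not match data")
        self.event_onsets = np.asarray(self.event_onsets, dtype=int)
        if self.event_onsets.size and (
            np.any(np.diff(self.event_onsets) <= 0)
            or self.event_onsets[0] < 0
            or self.event_onsets[-1] >= n_s
        ):
            raise ValueError("event onsets must be strictly increasing and in range")
        if self.bad_channels is None:
            self.bad_channels = np.zeros(n_el, dtype=bool)
        else:
            self.bad_channels = np.asarray(self.bad_channels, dtype=bool)
            if self.bad_channels.shape != (n_el,):
                raise ValueError("bad_channels mask must have one entry per electrode")
        if self.bad_segments is None:
            self.bad_segments = np.zeros(n_s, dtype=bool)
        else:
            self.bad_segments = np.asarray(self.bad_segments, dtype=bool)
            if self.bad_segments.shape != (n_s,):
                raise ValueError("bad_segments mask must have one entry per sample")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Trial-epoched data: trials x electrodes x samples.

    ``times`` is the time axis in ms relative to stimulus onset (spanning
    -500..+1000 ms by convention).  ``events`` carries one row of per-trial
    metadata (participant, trial, vot_ms, response, rt_ms) per trial, in
    order.  ``kind`` distinguishes z-scored high-gamma from raw voltage.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    events: pd.DataFrame
    electrodes: list[str] = field(default_factory=list)
    kind: str = "high-gamma-z"
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x samples")
        n_tr, n_el, n_s = self.data.shape
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (n_s,):
            raise ValueError("times must match the sample axis")
        if len(self.events) != n_tr:
            raise ValueError(
                f"events table has {len(self.events)} rows for {n_tr} trials"
            )
        if not self.electrodes:
            self.electrodes = [f"e{i}" for i in range(n_el)]
        if len(self.electrodes) != n_el:
            raise ValueError("electrode names do not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the first sample at/after ``t_ms``."""
        return int(np.searchsorted(self.times, t_ms - 1e-9))

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Samples with start_ms <= t <= stop_ms (inclusive ends)."""
        i0 = int(np.searchsorted(self.times, start_ms - 1e-9))
        i1 = int(np.searchsorted(self.times, stop_ms + 1e-9))
        return slice(i0, i1)

    def electrode_index(self, name: str) -> int:
        try:
            return self.electrodes.index(name)
        except ValueError:
            raise KeyError(f"unknown electrode {name!r}") from None

    @property
    def vots(self) -> np.ndarray:
        return self.events["vot_ms"].to_numpy(dtype=float)

    def mean_by_vot(self, electrode: int | str) -> dict[float, np.ndarray]:
        """Trial-averaged trace per VOT condition for one electrode."""
        if isinstance(electrode, str):
            electrode = self.electrode_index(electrode)
        out = {}
        vots = self.vots
        for vot in np.unique(vots):
            out[float(vot)] = self.data[vots == vot, electrode, :].mean(axis=0)
        return out

    def select_electrodes(self, which) -> "EpochSet":
        """Subset to a boolean mask, index list, or name list of electrodes."""
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.nonzero(which)[0]
        elif which.dtype.kind in ("U", "S", "O"):
            idx = np.array([self.electrode_index(str(n)) for n in which], dtype=int)
        else:
            idx = which.astype(int)
        return EpochSet(
            data=self.data[:, idx, :],
            sfreq=self.sfreq,
            times=self.times.copy(),
            events=self.events.copy(),
            electrodes=[self.electrodes[i] for i in idx],
            kind=self.kind,
            info=dict(self.info),
        )

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=data,
            sfreq=self.sfreq,
            times=self.times.copy(),
            events=self.events.copy(),
            electrodes=list(self.electrodes),
            kind=self.kind,
            info=dict(self.info),
        )


@dataclass
class Dataset:
    """A full synthetic (or loaded) study: per-participant epoch sets plus
    event and ground-truth tables.

    ``hg`` and ``lfp`` map participant id -> EpochSet.  ``truth`` records the
    generating parameters (true electrode class, tuning curve, onset slope,
    behavioral coefficients) so recovery can be scored.
    """

    hg: dict[str, EpochSet] = field(default_factory=dict)
    lfp: dict[str, EpochSet] = field(default_factory=dict)
    events: pd.DataFrame | None = None
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def participants(self) -> list[str]:
        keys = set(self.hg) | set(self.lfp)
        return sorted(keys)
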
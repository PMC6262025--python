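"""Core containers shared by every analysis stage.

All times are in seconds.  Parameters expressed in milliseconds by convention
(conduction delay, coincidence window, jitter range) are converted to seconds
at the boundary of each operation.  All windows and segments are half-open
``[start, stop)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognised recording regions.
REGIONS = ("V1", "dLGN")

#: Recognised stimulus conditions.
CONDITIONS = ("gray", "checkerboard")

#: Map kinds produced by the pipeline.
MAP_KINDS = ("percent_amplitude_change", "ppc", "correlation")

#: Spike times are considered distinct down to this resolution (seconds).
SPIKE_TIME_RESOLUTION_S = 5e-5


class ParameterError(ValueError):
    """A parameter violates a documented invariant."""


@dataclass
class LfpSignal:
    """One region's continuous LFP trace with sampling metadata.

    Parameters
    ----------
    samples : array of voltage samples (arbitrary units), uniformly sampled.
    fs : sampling rate in Hz.
    t0 : time of the first sample, seconds.
    region : recording-site label, one of ``REGIONS``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    region: str = "V1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("LFP samples must be one-dimensional")
        if not self.fs > 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ParameterError(f"non-finite LFP sample at index {bad}")
        if self.duration < 10.0:
            warnings.warn(
                f"LFP segment of {self.duration:.2f} s is short for spectral "
                "work (< 10 s); band estimates may be edge-dominated",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike times of a single unit (or a pooled region).

    ``span`` is the half-open recording interval the times live in.
    """

    times: np.ndarray
    region: str = "V1"
    unit_id: str = "u0"
    span: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ParameterError("spike times must be one-dimensional")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0])
            raise ParameterError(
                f"spike times of unit {self.unit_id} not strictly ascending "
                f"at index {bad + 1}"
            )
        lo, hi = self.span
        if self.times.size and (self.times[0] < lo or self.times[-1] > hi):
            raise ParameterError(
                f"spike times of unit {self.unit_id} fall outside span "
                f"[{lo}, {hi}]"
            )

    @property
    def n(self) -> int:
        return self.times.size

    def rate(self) -> float:
        lo, hi = self.span
        if not np.isfinite(hi):
            hi = self.times[-1] if self.times.size else lo
        dur = hi - lo
        return self.times.size / dur if dur > 0 else 0.0

    def shifted(self, dt: float) -> "SpikeTrain":
        lo, hi = self.span
        return SpikeTrain(self.times + dt, self.region, self.unit_id,
                          (lo + dt, hi + dt))


def pool_trains(trains: Sequence[SpikeTrain], region: str | None = None) -> SpikeTrain:
    """Pool several units of one region into a single train.

    Simultaneous spikes from different units are collapsed to single events at
    ``SPIKE_TIME_RESOLUTION_S`` so the pooled train stays strictly ascending.
    """
    if not trains:
        raise ParameterError("cannot pool an empty list of spike trains")
    region = region or trains[0].region
    merged = np.sort(np.concatenate([t.times for t in trains]))
    if merged.size:
        keep = np.concatenate(
            [[True], np.diff(merged) >= SPIKE_TIME_RESOLUTION_S])
        merged = merged[keep]
    lo = min(t.span[0] for t in trains)
    hi = max(t.span[1] for t in trains)
    return SpikeTrain(merged, region=region, unit_id="pooled", span=(lo, hi))


class EventTable:
    """Stimulus onsets with condition labels and durations.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``onset_s``, ``condition`` and ``duration_s``.
    """

    COLUMNS = ("onset_s", "condition", "duration_s")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"event table missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad:
            raise ParameterError(
                f"unknown condition labels {bad}; expected one of {CONDITIONS}")
        onsets = df["onset_s"].to_numpy(dtype=float)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ParameterError("event onsets must be strictly increasing")
        self.df = df

    @classmethod
    def from_arrays(cls, onsets: Iterable[float],
                    condition: str = "checkerboard",
                    duration_s: float = 0.1) -> "EventTable":
        onsets = np.asarray(list(onsets), dtype=float)
        return cls(pd.DataFrame({
            "onset_s": onsets,
            "condition": condition,
            "duration_s": duration_s,
        }))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy(dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.df["duration_s"].to_numpy(dtype=float)

    def select(self, condition: str) -> "EventTable":
        return EventTable(self.df[self.df["condition"] == condition])

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class TimeFrequencyMap:
    """Frequency x time grid of amplitude change, PPC or correlation values.

    ``times`` are seconds relative to event onset (negative = pre-stimulus).
    The unit of ``values`` depends on ``kind``: percent for
    ``percent_amplitude_change``, dimensionless in [-1/(N-1), 1] for ``ppc``
    and in [-1, 1] for ``correlation``.
    """

    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray
    kind: str
    baseline_window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.kind not in MAP_KINDS:
            raise ParameterError(f"unknown map kind {self.kind!r}")
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ParameterError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.freqs.size} freqs x {self.times.size} times")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("map times must be strictly increasing")
        if self.kind == "correlation":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
                raise ParameterError("correlation values must lie in [-1, 1]")

    def row(self, freq: float) -> np.ndarray:
        """Return the values at the frequency closest to ``freq``."""
        i = int(np.argmin(np.abs(self.freqs - freq)))
        return self.values[i]

    def peak_frequency(self,
                       time_range: tuple[float, float] | None = None
                       ) -> float:
        """Frequency of the map's peak: argmax over frequency of the map
        averaged over ``time_range`` (or all latencies).  Averaging over
        time before taking the argmax makes the estimate robust to
        single-pixel noise."""
        if time_range is None:
            sel = np.ones(self.times.size, dtype=bool)
        else:
            sel = (self.times >= time_range[0]) & (self.times < time_range[1])
        if not sel.any():
            raise ParameterError("time_range selects no latencies")
        profile = np.nanmean(self.values[:, sel], axis=1)
        return float(self.freqs[int(np.nanargmax(profile))])

    def to_hdf5(self, path: str | Path, name: str = "map") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("freqs", data=self.freqs)
            g.create_dataset("times", data=self.times)
            g.create_dataset("values", data=self.values)
            g.attrs["kind"] = self.kind
            if self.baseline_window is not None:
                g.attrs["baseline_window"] = self.baseline_window
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str, np.integer, np.floating)):
                    g.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path, name: str = "map") -> "TimeFrequencyMap":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[name]
            bw = g.attrs.get("baseline_window")
            return cls(
                freqs=g["freqs"][:],
                times=g["times"][:],
                values=g["values"][:],
                kind=str(g.attrs["kind"]),
                baseline_window=tuple(bw) if bw is not None else None,
                meta={k: g.attrs[k] for k in g.attrs
                      if k not in ("kind", "baseline_window")},
            )
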
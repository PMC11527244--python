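"""Cleaning and resampling of beat-timed RR-interval series.

Ectopic beats and artifacts are detected with a running-median deviation rule
and replaced by linear interpolation between the nearest valid neighbours;
the tachogram is then resampled onto a uniform grid (4 Hz for the epoch-based
features, 8 Hz for the spectral features) by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RRSeries:
    """Beat-timed RR intervals.

    ``beat_times[i]`` is the time (s) of the beat *ending* the interval
    ``intervals[i]`` (ms); for a clean series the beat times are the
    cumulative sums of the intervals from the series start.
    """

    beat_times: np.ndarray   # s, strictly increasing
    intervals: np.ndarray    # ms, > 0
    case_id: str = ""

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", rr)
        if bt.shape != rr.shape or bt.ndim != 1:
            raise ValueError("beat_times and intervals must be 1-D and aligned")
        if len(bt) and np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_intervals(cls, intervals, t_start: float = 0.0, case_id: str = "") -> "RRSeries":
        """Build a series from intervals alone; beat times are cumulative sums."""
        rr = np.asarray(intervals, dtype=float)
        times = t_start + np.cumsum(rr) / 1000.0
        return cls(times, rr, case_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.beat_times, "rr_ms": self.intervals})

    @classmethod
    def from_csv(cls, path, case_id: str = "", timestamp: str = "beat") -> "RRSeries":
        """Read an RR CSV with columns ``time_s,rr_ms``.

        ``timestamp`` states the exporter's convention: ``"beat"`` if the
        time column marks the beat ending each interval, ``"interval_start"``
        if it marks the interval onset (times are then shifted by one
        interval).
        """
        df = pd.read_csv(path)
        missing = {"time_s", "rr_ms"} - set(df.columns)
        if missing:
            raise ValueError(f"RR CSV {path} is missing columns {sorted(missing)}")
        t = df["time_s"].to_numpy(float)
        rr = df["rr_ms"].to_numpy(float)
        if timestamp == "interval_start":
            t = t + rr / 1000.0
        elif timestamp != "beat":
            raise ValueError("timestamp must be 'beat' or 'interval_start'")
        return cls(t, rr, case_id)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class UniformSeries:
    """A tachogram resampled on a uniform grid."""

    start_time: float   # s
    rate: float         # Hz
    values: np.ndarray  # ms

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("resampled values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate


@dataclass
class ArtifactMask:
    """Per-beat artifact flags with the rule parameters that produced them."""

    flags: np.ndarray
    threshold: float
    window: int
    positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.positions = np.flatnonzero(self.flags)


def detect_artifacts(rr: RRSeries, threshold: float = 0.2, window: int = 11) -> ArtifactMask:
    """Flag beats deviating from the running median of ``window`` neighbours.

    A beat is flagged when its interval differs from the median of the
    ``window`` surrounding intervals by more than ``threshold`` (a fraction
    of that median). Deterministic; the median window is centred and clipped
    at the series ends.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    n = len(rr)
    if n <= window:
        raise ValueError(f"series of {n} beats is shorter than the {window}-beat window")
    x = rr.intervals
    half = window // 2
    med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med[i] = np.median(x[lo:hi])
    flags = np.abs(x - med) > threshold * med
    return ArtifactMask(flags, threshold, window)


def interpolate_artifacts(rr: RRSeries, mask: ArtifactMask) -> RRSeries:
    """Replace flagged intervals by linear interpolation between valid neighbours.

    Beat times are rebuilt as cumulative sums from the original series start
    (the time of the first beat minus its interval). Flagged endpoints take
    the nearest valid value. Unflagged intervals are unchanged.
    """
    flags = mask.flags
    if len(flags) != len(rr):
        raise ValueError("mask is not aligned with the series")
    if flags.all():
        raise ValueError("all beats are flagged; nothing to interpolate from")
    if not flags.any():
        return rr
    x = rr.intervals.astype(float).copy()
    idx = np.arange(len(x))
    good = ~flags
    x[flags] = np.interp(idx[flags], idx[good], x[good])
    t0 = rr.beat_times[0] - rr.intervals[0] / 1000.0
    return RRSeries.from_intervals(x, t_start=t0, case_id=rr.case_id)


def clean(rr: RRSeries, threshold: float = 0.2, window: int = 11) -> tuple[RRSeries, ArtifactMask]:
    """Detect-and-interpolate convenience wrapper."""
    mask = detect_artifacts(rr, threshold, window)
    return interpolate_artifacts(rr, mask), mask


def resample(rr: RRSeries, rate: float) -> UniformSeries:
    """Linearly interpolate the tachogram onto a uniform grid.

    The grid spans ``[first beat time, last beat time]`` with spacing
    ``1/rate``; both endpoints are included when they fall on the grid, so
    the output has ``floor((t_last - t_first) * rate) + 1`` samples.
    """
    if len(rr) < 2:
        raise ValueError("resampling needs at least 2 beats")
    t0, t1 = rr.beat_times[0], rr.beat_times[-1]
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    values = np.interp(grid, rr.beat_times, rr.intervals)
    return UniformSeries(start_time=t0, rate=rate, values=values)


def artifact_report(original: RRSeries, cleaned: RRSeries, mask: ArtifactMask) -> pd.DataFrame:
    """Table of replaced beats: ``beat_index,original_ms,replaced_ms``."""
    pos = mask.positions
    return pd.DataFrame(
        {
            "beat_index": pos,
            "original_ms": original.intervals[pos],
            "replaced_ms": cleaned.intervals[pos],
        }
    )
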
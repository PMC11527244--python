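"""T0 detection on the BIS trace and time-point measurement extraction.

T0 anchors the analysis: it is the first BIS sample at or above 60 after the
anaesthetic drug targets are set to zero. HRV measurements are collected at
T-30, T-20, T-10, T-5, T0, T+2 and T+5 minutes and each row is labeled
"BIS>=60" or "BIS<60" by the BIS value at that time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    FEATURE_NAMES,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    AnalysisConfig,
)


class NoAwakeningError(ValueError):
    """The BIS never reaches the threshold after drug stop (excluded recording)."""


@dataclass(frozen=True)
class BISTrace:
    """A depth-of-hypnosis trace sampled (nominally at 1 Hz) over the case."""

    times: np.ndarray   # s, increasing
    values: np.ndarray  # 0-100

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and aligned")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be increasing")
        if np.any((v < 0) | (v > 100)):
            raise ValueError("BIS values must lie in [0, 100]")

    @classmethod
    def from_csv(cls, path) -> "BISTrace":
        df = pd.read_csv(path)
        missing = {"time_s", "bis"} - set(df.columns)
        if missing:
            raise ValueError(f"BIS CSV {path} is missing columns {sorted(missing)}")
        return cls(df["time_s"].to_numpy(float), df["bis"].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "bis": self.values}).to_csv(path, index=False)

    def value_at(self, time: float, mode: str = "instantaneous") -> float:
        """BIS at a time point: nearest sample, or median of the trailing 60 s."""
        if time < self.times[0] or time > self.times[-1]:
            raise ValueError(f"time {time} outside the trace span")
        if mode == "instantaneous":
            i = int(np.argmin(np.abs(self.times - time)))
            return float(self.values[i])
        if mode == "median60":
            sel = (self.times > time - 60.0) & (self.times <= time)
            return float(np.median(self.values[sel]))
        raise ValueError(f"unknown BIS sampling mode {mode!r}")


def detect_t0(bis: BISTrace, drug_stop: float, threshold: float = 60.0) -> float:
    """Time of the first BIS sample >= threshold at or after ``drug_stop``.

    Raises :class:`NoAwakeningError` when the trace never reaches the
    threshold after drug stop — the situation of the recordings excluded
    from the study because the electrode was removed before awakening.
    """
    if drug_stop < bis.times[0] or drug_stop > bis.times[-1]:
        raise ValueError("drug_stop outside the trace span")
    after = bis.times >= drug_stop
    hit = after & (bis.values >= threshold)
    if not hit.any():
        raise NoAwakeningError(
            f"BIS never reaches {threshold} after drug stop at {drug_stop} s: "
            "no awakening captured"
        )
    return float(bis.times[np.argmax(hit)])


def label(bis_value: float, threshold: float = 60.0) -> str:
    """Class label for a measurement row: "BIS>=60" iff BIS >= threshold."""
    if bis_value is None or not np.isfinite(bis_value):
        raise ValueError("missing BIS value; cannot label the row")
    return POSITIVE_LABEL if bis_value >= threshold else NEGATIVE_LABEL


def extract_measurements(
    tracks: pd.DataFrame,
    bis: BISTrace,
    t0: float,
    case_id: str = "",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Measurement rows for one case at the seven study time points.

    ``tracks`` is the 3-minute-averaged feature frame from
    :func:`hrvarousal.features.sliding_features`. A time point is emitted
    only when every feature is available there and the BIS trace covers it;
    otherwise it is silently omitted (post-T0 points are frequently missing
    when the recording ends at extubation).
    """
    config = config or AnalysisConfig()
    rows = []
    for tp in config.timepoints_min:
        t = t0 + tp * 60.0
        if t < tracks.index[0] or t > tracks.index[-1]:
            continue
        # nearest grid time (the grid is 1 s, so this is within 0.5 s)
        i = int(np.argmin(np.abs(tracks.index.to_numpy() - t)))
        feat = tracks.iloc[i]
        if feat.isna().any():
            continue
        if t < bis.times[0] or t > bis.times[-1]:
            continue
        bis_value = bis.value_at(t, config.bis_at_timepoint)
        if tp == 0:
            # T0 is by definition the first crossing; the label is positive
            # regardless of the smoothing mode used for the BIS column.
            bis_value = max(bis_value, bis.value_at(t, "instantaneous"))
        row = {"case_id": case_id, "timepoint_min": tp}
        row.update({name: float(feat[name]) for name in FEATURE_NAMES})
        row["BIS"] = bis_value
        row["class"] = label(bis_value, config.bis_threshold)
        rows.append(row)
    cols = ["case_id", "timepoint_min", *FEATURE_NAMES, "BIS", "class"]
    return pd.DataFrame(rows, columns=cols)


def timepoint_counts(table: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-time-point availability and positive-label counts (design table)."""
    config = config or AnalysisConfig()
    out = []
    for tp in config.timepoints_min:
        sub = table[table["timepoint_min"] == tp]
        out.append(
            {
                "timepoint_min": tp,
                "available": len(sub),
                "positive": int((sub["class"] == POSITIVE_LABEL).sum()),
            }
        )
    return pd.DataFrame(out)
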
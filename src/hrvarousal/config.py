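"""Analysis configuration: every window length, band, threshold and rate in one place.

The defaults reproduce the published study design: HRV features on native
windows (100 beats for RMSSD/SDNN/HR, 60 s for STV/LTV, 64 s for the spectral
features), re-evaluated on a common 1 s slide grid and smoothed by a trailing
3-minute average; measurements at seven time points anchored on T0 (the first
time the BIS reaches 60 after the hypnotic/opioid targets are set to zero);
bootstrap-stepwise logistic selection with 500 replicates and a 70% retention
rule; probability classification threshold 0.39.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from typing import Literal

#: Measurement time points relative to T0, in minutes.
TIMEPOINTS_MIN = (-30, -20, -10, -5, 0, 2, 5)

#: The eight HRV variables in their canonical column order.
FEATURE_NAMES = ("HR", "ANI", "STV", "SDNN", "LTV", "RMSSD", "LF", "HF")

POSITIVE_LABEL = "BIS>=60"
NEGATIVE_LABEL = "BIS<60"


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry for the sliding HRV feature computation."""

    rmssd_sdnn_len: int = 100          # beats
    stv_ltv_len: float = 60.0          # s
    spectral_len: float = 64.0         # s
    slide: float = 1.0                 # s
    average_len: float = 180.0         # s, trailing moving average
    epoch_len: float = 3.75            # s
    n_epochs: int = 16
    resample_time_domain: float = 4.0  # Hz, for STV/LTV epoch means
    resample_spectral: float = 8.0     # Hz, for LF/HF/ANI
    lf_band: tuple[float, float] = (0.05, 0.15)   # Hz
    hf_band: tuple[float, float] = (0.15, 0.4)    # Hz

    def __post_init__(self) -> None:
        if abs(self.n_epochs * self.epoch_len - self.stv_ltv_len) > 1e-9:
            raise ValueError("n_epochs * epoch_len must equal stv_ltv_len")
        if not (self.lf_band[0] < self.lf_band[1] <= self.hf_band[0] < self.hf_band[1]):
            raise ValueError("LF and HF bands must be disjoint and ordered")

    @property
    def stv_ltv_samples(self) -> int:
        return int(round(self.stv_ltv_len * self.resample_time_domain))

    @property
    def spectral_samples(self) -> int:
        return int(round(self.spectral_len * self.resample_spectral))


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the pipeline."""

    windows: WindowSpec = field(default_factory=WindowSpec)

    # Artifact filter (running-median deviation rule).
    artifact_threshold: float = 0.2    # fractional deviation from local median
    artifact_window: int = 11          # beats

    # ANI scaling constants (from the index's originating publications).
    ani_alpha: float = 5.1
    ani_beta: float = 1.2
    ani_divisor: float = 12.8

    # Epoching.
    bis_threshold: float = 60.0
    timepoints_min: tuple[int, ...] = TIMEPOINTS_MIN
    bis_at_timepoint: Literal["instantaneous", "median60"] = "instantaneous"

    # Variable selection.
    loading_cutoff: float = 0.6
    corr_cutoff: float = 0.70
    n_factors: int | None = None       # None -> Kaiser rule (eigenvalues > 1)

    # Modeling.
    bootstrap_replicates: int = 500
    removal_alpha: float = 0.05
    retention_threshold: float = 0.70
    classification_threshold: float = 0.39
    spline_knot_quantiles: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95)
    alpha: float = 0.05

    # CART hyperparameters.
    cart_min_split: int = 20
    cart_min_leaf: int = 7
    cart_min_improvement: float = 0.01

    seed: int = 0

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in run outputs."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
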
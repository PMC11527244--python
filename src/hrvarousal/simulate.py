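"""Synthetic RR/BIS recordings and measurement tables.

The RR generator uses an additive two-sinusoid model,

    RR(t) = baseline + a_LF(t) sin(2 pi f_LF t) + a_HF(t) sin(2 pi f_HF t) + e(t),

with white Gaussian noise e(t) and amplitudes that switch from the
anesthetized to the pre-arousal state over a linear transition window at the
time the hypnotic/opioid targets are set to zero. It is a stand-in for the
autonomic modulation of the sinus node, not a physiological model: it makes
LF/HF band separation, ANI monotonicity and the class-conditional ordering
of the HRV features testable, nothing more. The default amplitudes are
calibrated so that the class-conditional SDNN medians of a simulated cohort
match the study population (about 24 ms under anaesthesia, 31 ms in
pre-arousal periods); the default HF frequency (0.2 Hz) is the ventilator
rate of 12 breaths/min, and the default heart rate (~65 min^-1) matches the
cohort mean.

The BIS trace is a sigmoid ramp from a maintenance plateau below 60 to a
recovery plateau above 60, positioned so that the first 1 Hz sample at or
above 60 falls exactly at the requested T0 (when T0 is grid-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import FEATURE_NAMES, NEGATIVE_LABEL, POSITIVE_LABEL, TIMEPOINTS_MIN
from .epoching import BISTrace
from .preprocess import RRSeries


@dataclass(frozen=True)
class SimCaseParams:
    """Parameters of one simulated case."""

    duration: float = 2640.0      # s
    baseline_rr: float = 926.0    # ms  (~65 min^-1)
    lf_amp: float = 22.0          # ms
    hf_amp: float = 12.0          # ms
    lf_freq: float = 0.1          # Hz
    hf_freq: float = 0.2          # Hz (ventilation at 12 min^-1)
    noise_sd: float = 16.0        # ms
    ectopic_rate: float = 0.0     # fraction of beats
    t0: float = 2220.0            # s, time BIS first reaches 60
    drug_stop: float = 1800.0     # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.baseline_rr <= 0:
            raise ValueError("duration and baseline_rr must be positive")
        if not (0 <= self.ectopic_rate < 0.2):
            raise ValueError("ectopic_rate must be in [0, 0.2)")
        if not (self.drug_stop < self.t0 < self.duration):
            raise ValueError("need drug_stop < t0 < duration")
        if min(self.lf_amp, self.hf_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class SimStateProfile:
    """Per-state modulation multipliers and the BIS trajectory shape.

    Pre-arousal multipliers default to 1.3: autonomic variability recovers
    ahead of cortical arousal, so SDNN/LTV/LF/HF run higher in BIS>=60
    periods.
    """

    lf_mult: tuple[float, float] = (1.0, 1.3)      # (anesthetized, pre-arousal)
    hf_mult: tuple[float, float] = (1.0, 1.3)
    noise_mult: tuple[float, float] = (1.0, 1.3)
    transition_s: float = 120.0                    # amplitude cross-fade at drug_stop
    bis_low: float = 45.0
    bis_high: float = 75.0
    bis_ramp_width: float = 120.0                  # 10-90% rise time, s

    def __post_init__(self) -> None:
        if not (self.bis_low < 60 <= self.bis_high):
            raise ValueError("need bis_low < 60 <= bis_high")
        for pair in (self.lf_mult, self.hf_mult, self.noise_mult):
            if min(pair) <= 0:
                raise ValueError("state multipliers must be positive")


def _state_weight(t: np.ndarray | float, drug_stop: float, transition: float):
    """0 before drug_stop, 1 after drug_stop + transition, linear between."""
    if transition <= 0:
        return np.where(np.asarray(t) >= drug_stop, 1.0, 0.0)
    return np.clip((np.asarray(t) - drug_stop) / transition, 0.0, 1.0)


def simulate_rr(params: SimCaseParams, profile: SimStateProfile | None = None,
                case_id: str = "") -> RRSeries:
    """Generate a beat-timed RR series under the two-state sinusoid model."""
    profile = profile or SimStateProfile()
    rng = np.random.default_rng(params.seed)
    n_max = int(np.ceil(params.duration / (params.baseline_rr / 1000.0) * 2)) + 16
    noise = rng.normal(0.0, 1.0, size=n_max)

    times: list[float] = []
    intervals: list[float] = []
    t = 0.0
    i = 0
    while True:
        w = float(_state_weight(t, params.drug_stop, profile.transition_s))
        a_lf = params.lf_amp * (profile.lf_mult[0] + w * (profile.lf_mult[1] - profile.lf_mult[0]))
        a_hf = params.hf_amp * (profile.hf_mult[0] + w * (profile.hf_mult[1] - profile.hf_mult[0]))
        sd = params.noise_sd * (
            profile.noise_mult[0] + w * (profile.noise_mult[1] - profile.noise_mult[0])
        )
        rr = (
            params.baseline_rr
            + a_lf * np.sin(2 * np.pi * params.lf_freq * t)
            + a_hf * np.sin(2 * np.pi * params.hf_freq * t)
            + sd * noise[i]
        )
        if rr <= 0:
            raise ValueError(
                "parameters produced a non-positive RR interval; "
                "reduce amplitudes/noise relative to baseline_rr"
            )
        t += rr / 1000.0
        if t > params.duration:
            break
        times.append(t)
        intervals.append(rr)
        i += 1
    return RRSeries(np.array(times), np.array(intervals), case_id)


def inject_artifacts(rr: RRSeries, rate: float, seed: int) -> tuple[RRSeries, np.ndarray]:
    """Corrupt a fraction of beats with ectopic pairs or spikes.

    Each corrupted position is either the first beat of a premature +
    compensatory pair (intervals x0.5 then x1.5) or, when it is the last
    beat, a lone x2 spike. Returns the corrupted series and the sorted array
    of corrupted beat indices (pairs contribute both indices).
    """
    if not (0 <= rate < 0.2):
        raise ValueError("artifact rate must be in [0, 0.2)")
    if rate == 0:
        return rr, np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    n = len(rr)
    n_hits = int(round(rate * n))
    hits = rng.choice(n, size=n_hits, replace=False)
    x = rr.intervals.copy()
    corrupted: set[int] = set()
    for h in sorted(hits):
        if h in corrupted:
            continue
        if h + 1 < n and (h + 1) not in corrupted:
            x[h] *= 0.5
            x[h + 1] *= 1.5
            corrupted.update((h, h + 1))
        else:
            x[h] *= 2.0
            corrupted.add(h)
    t0 = rr.beat_times[0] - rr.intervals[0] / 1000.0
    out = RRSeries.from_intervals(x, t_start=t0, case_id=rr.case_id)
    return out, np.array(sorted(corrupted))


def simulate_bis(params: SimCaseParams, profile: SimStateProfile | None = None) -> BISTrace:
    """Generate the 1 Hz BIS trace with its first >= 60 sample at ``params.t0``."""
    profile = profile or SimStateProfile()
    if profile.bis_high <= 60:
        raise ValueError("bis_high must exceed 60 for the trace to cross the threshold")
    lo, hi = profile.bis_low, profile.bis_high
    scale = profile.bis_ramp_width / (2 * np.log(9.0))  # 10-90% rise over ramp_width
    q = (60.0 - lo) / (hi - lo)
    center = params.t0 - scale * np.log(q / (1 - q))    # sigmoid hits 60 exactly at t0
    t = np.arange(0.0, np.floor(params.duration) + 1.0)
    values = lo + (hi - lo) / (1.0 + np.exp(-(t - center) / scale))
    return BISTrace(t, np.clip(values, 0.0, 100.0))


def simulate_case(params: SimCaseParams, profile: SimStateProfile | None = None,
                  case_id: str = "") -> tuple[RRSeries, BISTrace, float]:
    profile = profile or SimStateProfile()
    rr = simulate_rr(params, profile, case_id)
    if params.ectopic_rate > 0:
        rr, _ = inject_artifacts(rr, params.ectopic_rate, params.seed + 1)
    return rr, simulate_bis(params, profile), params.drug_stop


def simulate_cohort(
    n_cases: int = 34,
    profile: SimStateProfile | None = None,
    seed: int = 0,
    base_params: SimCaseParams | None = None,
) -> list[tuple[RRSeries, BISTrace, float]]:
    """Independent cases with jittered per-case parameters.

    Baseline RR, modulation amplitudes and T0 are jittered across cases; the
    recording end is T0 plus a log-normal margin (median ~4 min, matching
    the study's spread of extubation delays), so some cases do not cover the
    T+2 / T+5 points — the same attrition pattern as the study design.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    profile = profile or SimStateProfile()
    base = base_params or SimCaseParams()
    rng = np.random.default_rng(seed)
    cases = []
    for k in range(n_cases):
        t0 = float(rng.uniform(2150.0, 2400.0))
        post_min = float(np.clip(rng.lognormal(mean=1.381, sigma=1.509), 0.5, 8.0))
        params = replace(
            base,
            baseline_rr=float(np.clip(rng.normal(base.baseline_rr, 70.0), 600.0, 1300.0)),
            lf_amp=base.lf_amp * float(rng.lognormal(0.0, 0.2)),
            hf_amp=base.hf_amp * float(rng.lognormal(0.0, 0.2)),
            noise_sd=base.noise_sd * float(rng.lognormal(0.0, 0.15)),
            t0=np.floor(t0),
            drug_stop=np.floor(t0) - 420.0,
            duration=np.floor(t0) + post_min * 60.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(simulate_case(params, profile, case_id=f"case{k:02d}"))
    return cases


# ---------------------------------------------------------------------------
# tabular generators (direct inputs for the selection/modeling stages)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTableSim:
    """A simulated measurement table together with its generating truth."""

    table: pd.DataFrame
    coef: dict[str, float]     # true logistic coefficients (on the latent scale)
    intercept: float


def simulate_feature_table(
    n_rows: int,
    effects: dict[str, float],
    seed: int,
    *,
    corr: np.ndarray | None = None,
    intercept: float = 0.0,
    lognormal: tuple[str, ...] = (),
    scales: dict[str, tuple[float, float]] | None = None,
) -> FeatureTableSim:
    """Rows with correlated features and a class from a stated logistic model.

    Latent variables Z are standard multivariate normal with correlation
    ``corr`` (identity by default); the class is Bernoulli with
    ``logit p = intercept + sum(effects[v] * Z_v)``. Observed columns are
    ``loc + scale * Z`` (or ``exp`` of that for names in ``lognormal``, which
    makes the logit linear in log(x), not in x). ``scales`` maps a name to
    (loc, scale); default (0, 1).
    """
    if n_rows < 20:
        raise ValueError("n_rows must be >= 20")
    names = list(effects)
    p = len(names)
    rng = np.random.default_rng(seed)
    if corr is None:
        corr = np.eye(p)
    corr = np.asarray(corr, dtype=float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate covariance for the latent features") from exc
    z = rng.standard_normal((n_rows, p)) @ chol.T
    beta = np.array([effects[v] for v in names])
    logit = intercept + z @ beta
    y = rng.random(n_rows) < 1.0 / (1.0 + np.exp(-logit))

    scales = scales or {}
    data = {}
    for j, v in enumerate(names):
        loc, scale = scales.get(v, (0.0, 1.0))
        col = loc + scale * z[:, j]
        data[v] = np.exp(col) if v in lognormal else col
    df = pd.DataFrame(data)
    df.insert(0, "case_id", [f"r{i}" for i in range(n_rows)])
    df["class"] = np.where(y, POSITIVE_LABEL, NEGATIVE_LABEL)
    return FeatureTableSim(df, dict(zip(names, beta)), intercept)


# Class-conditional marginals calibrated to the study's HRV summary table:
# log-normal (median, IQR-derived log-sd, log-shift in BIS>=60 periods) for
# the skewed variability features, normal (mean, sd, shift) for HR and ANI.
_STUDY_MARGINALS = {
    #            median_or_mean  log_sd_or_sd   positive-class shift
    "SDNN": ("lognormal", 24.27, 0.533, 0.241),
    "RMSSD": ("lognormal", 16.94, 0.833, 0.231),
    "LTV": ("lognormal", 64.52, 0.510, 0.341),
    "STV": ("lognormal", 6.81, 0.572, 0.282),
    "LF": ("lognormal", 0.17, 1.443, 0.534),
    "HF": ("lognormal", 0.03, 1.443, 0.693),
    "HR": ("normal", 64.79, 13.1, 1.03),
    "ANI": ("normal", 68.78, 17.12, -7.13),
}

# Latent factor loadings used to correlate the eight features: one
# variability factor, one spectral factor, one autonomic-tone factor.
_STUDY_LOADINGS = {
    "SDNN": (0.95, 0.15, 0.0),
    "RMSSD": (0.88, 0.25, 0.1),
    "LTV": (0.92, 0.05, -0.1),
    "STV": (0.93, 0.10, 0.0),
    "LF": (0.25, 0.92, 0.0),
    "HF": (0.20, 0.93, -0.05),
    "HR": (-0.10, 0.0, -0.65),
    "ANI": (-0.10, 0.0, 0.75),
}

#: Per-time-point availability and positive counts of the study design.
STUDY_DESIGN = pd.DataFrame(
    {
        "timepoint_min": TIMEPOINTS_MIN,
        "available": (34, 34, 34, 34, 34, 23, 15),
        "positive": (1, 0, 0, 1, 34, 21, 13),
    }
)


def simulate_study_table(seed: int = 0, n_cases: int = 34) -> pd.DataFrame:
    """A measurement table with the study's exact design shape.

    Rows follow the published availability pattern (all cases at T-30..T0,
    23 at T+2, 15 at T+5 when ``n_cases`` is 34) and label pattern (all T0
    rows positive, sporadic pre-T0 positives, most post-T0 rows positive).
    Features are drawn from class-conditional, factor-correlated marginals
    calibrated to the study's summary statistics; BIS is drawn consistently
    with the label. For other ``n_cases`` the pattern is scaled
    proportionally.
    """
    rng = np.random.default_rng(seed)
    design = STUDY_DESIGN
    if n_cases != 34:
        frac = n_cases / 34.0
        design = design.assign(
            available=np.minimum(np.round(design["available"] * frac).astype(int), n_cases),
            positive=np.round(design["positive"] * frac).astype(int),
        )

    rows = []
    names = list(FEATURE_NAMES)
    loadings = np.array([_STUDY_LOADINGS[v] for v in names])
    uniq = np.sqrt(np.clip(1.0 - np.sum(loadings**2, axis=1), 0.05, None))
    for _, spec_row in design.iterrows():
        tp = int(spec_row["timepoint_min"])
        avail = int(spec_row["available"])
        pos = int(spec_row["positive"])
        # cases are ordered by recording length, so the first `avail` cover tp
        for c in range(avail):
            is_pos = (
                c < pos if tp > 0 else (c == avail - 1 if pos else False)
            ) or tp == 0
            factors = rng.standard_normal(3)
            eps = rng.standard_normal(len(names))
            z = loadings @ factors + uniq * eps
            row = {"case_id": f"case{c:02d}", "timepoint_min": tp}
            for v, zv in zip(names, z):
                kind, center, sd, shift = _STUDY_MARGINALS[v]
                if kind == "lognormal":
                    row[v] = float(np.exp(np.log(center) + (shift if is_pos else 0.0) + sd * zv))
                else:
                    row[v] = float(center + (shift if is_pos else 0.0) + sd * zv)
            row["ANI"] = float(np.clip(row["ANI"], 0.0, 100.0))
            if is_pos:
                row["BIS"] = float(np.clip(60.0 + rng.lognormal(np.log(6.0), 0.7), 60.0, 100.0))
            else:
                row["BIS"] = float(np.clip(rng.normal(41.6, 9.5), 5.0, 59.9))
            row["class"] = POSITIVE_LABEL if is_pos else NEGATIVE_LABEL
            rows.append(row)
    cols = ["case_id", "timepoint_min", *names, "BIS", "class"]
    return pd.DataFrame(rows)[cols]
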
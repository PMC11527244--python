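"""The eight HRV variables: HR, ANI, STV, SDNN, LTV, RMSSD, LF, HF.

Each variable is computed on its native window — 100 beats for RMSSD/SDNN/HR,
60 s (sixteen 3.75 s epochs of the 4 Hz tachogram) for STV/LTV, 64 s of the
8 Hz tachogram for the wavelet-spectral LF/HF and the envelope-based ANI —
re-evaluated at every step of a common 1 s slide grid and smoothed with a
trailing 3-minute moving average. All windows are trailing (they end at the
grid time), which makes the whole track causal.

LF/HF are mean-squared energies of Daubechies wavelet-packet band-pass
reconstructions over the [0.05-0.15] Hz and [0.15-0.4] Hz bands, with
fractional-overlap weighting of the packet leaves straddling a band edge.
ANI measures the relative magnitude of the HF oscillation
(respiratory sinus arrhythmia) as the minimal area between the upper and
lower envelopes of the HF-band-filtered, unit-energy-normalized tachogram
over four 16 s sub-windows, mapped to a 0-100 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt

from .config import FEATURE_NAMES, WindowSpec
from .preprocess import RRSeries, UniformSeries, resample

_WAVELET = "db8"
_MODE = "symmetric"


# ---------------------------------------------------------------------------
# time-domain operators
# ---------------------------------------------------------------------------

def rmssd(window: np.ndarray) -> float:
    """Root mean square of successive RR differences (ms)."""
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(w)
    return float(np.sqrt(np.mean(d * d)))


def sdnn(window: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of RR intervals (ms)."""
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("SDNN needs at least 2 intervals")
    return float(np.std(w, ddof=1))


def heart_rate(window: np.ndarray) -> float:
    """Mean heart rate (min^-1) of an RR window: 60000 / mean(RR)."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("heart rate needs at least 1 interval")
    return float(60000.0 / np.mean(w))


def epoch_means(window: np.ndarray, n_epochs: int = 16) -> np.ndarray:
    """Means of consecutive equal-length epochs of a uniform 60 s window.

    The canonical call divides 240 samples (60 s at 4 Hz) into sixteen
    3.75 s epochs of 15 samples each.
    """
    w = np.asarray(window, dtype=float)
    if w.size % n_epochs:
        raise ValueError(f"window of {w.size} samples does not split into {n_epochs} epochs")
    return w.reshape(n_epochs, -1).mean(axis=1)


def stv(means: np.ndarray) -> float:
    """Short-term variation: mean absolute difference between successive epoch means."""
    m = np.asarray(means, dtype=float)
    if m.size != 16:
        raise ValueError("STV expects 16 epoch means")
    return float(np.mean(np.abs(np.diff(m))))


def ltv(means: np.ndarray) -> float:
    """Long-term variation: range (max - min) of the 16 epoch means."""
    m = np.asarray(means, dtype=float)
    if m.size != 16:
        raise ValueError("LTV expects 16 epoch means")
    return float(m.max() - m.min())


# ---------------------------------------------------------------------------
# spectral operators (Daubechies wavelet packets at 8 Hz on 64 s windows)
# ---------------------------------------------------------------------------
#
# The LF/HF band edges (0.05/0.15/0.4 Hz) do not align with the dyadic level
# boundaries of a plain DWT, and the level straddling 0.15 Hz would smear a
# respiratory tone across both bands. Band energies are therefore computed
# from a depth-6 wavelet packet decomposition (terminal bands 0.0625 Hz wide
# at 8 Hz) with the db8 wavelet, whose longer filters keep the band edges
# sharp: the packet leaves overlapping the band are scaled by the square
# root of their fractional overlap and the band-passed signal is
# reconstructed; the band energy is its mean square (ms^2).

_PACKET_LEVEL = 6
_paths_cache: dict[int, list[str]] = {}


def _freq_ordered_paths(level: int = _PACKET_LEVEL) -> list[str]:
    """Packet leaf paths in natural frequency order (Gray-code permutation)."""
    if level not in _paths_cache:
        wp = pywt.WaveletPacket(np.zeros(2 ** (level + 3)), _WAVELET, mode=_MODE,
                                maxlevel=level)
        _paths_cache[level] = [n.path for n in wp.get_level(level, order="freq")]
    return _paths_cache[level]


def _packet_decompose(x: np.ndarray, level: int = _PACKET_LEVEL) -> dict[str, np.ndarray]:
    nodes = {"": np.asarray(x, dtype=float)}
    frontier = [""]
    for _ in range(level):
        nxt = []
        for p in frontier:
            ca, cd = pywt.dwt(nodes[p], _WAVELET, mode=_MODE, axis=-1)
            nodes[p + "a"], nodes[p + "d"] = ca, cd
            nxt += [p + "a", p + "d"]
        frontier = nxt
    return nodes


def _packet_reconstruct(nodes: dict[str, np.ndarray], leaf_weights: dict[str, float],
                        level: int = _PACKET_LEVEL) -> np.ndarray:
    rec = {p: nodes[p] * w for p, w in leaf_weights.items()}
    for lev in range(level, 0, -1):
        for par in sorted({p[:-1] for p in rec if len(p) == lev}):
            ca = rec.get(par + "a")
            cd = rec.get(par + "d")
            if ca is None:
                ca = np.zeros(nodes[par + "a"].shape)
            if cd is None:
                cd = np.zeros(nodes[par + "d"].shape)
            out = pywt.idwt(ca, cd, _WAVELET, mode=_MODE, axis=-1)
            rec[par] = out[..., : nodes[par].shape[-1]]
    return rec[""]


def _band_leaf_weights(band: tuple[float, float], rate: float,
                       level: int = _PACKET_LEVEL) -> dict[str, float]:
    paths = _freq_ordered_paths(level)
    width = (rate / 2) / len(paths)
    weights = {}
    for i, p in enumerate(paths):
        lo, hi = i * width, (i + 1) * width
        frac = max(0.0, min(band[1], hi) - max(band[0], lo)) / width
        if frac > 0:
            weights[p] = float(np.sqrt(frac))
    return weights


def band_filter(x: np.ndarray, band: tuple[float, float], rate: float = 8.0) -> np.ndarray:
    """Band-pass ``x`` (last axis = time) via the weighted packet reconstruction."""
    nodes = _packet_decompose(x)
    return _packet_reconstruct(nodes, _band_leaf_weights(band, rate))


def wavelet_band_energy(window, band: tuple[float, float], rate: float = 8.0) -> float:
    """Mean squared energy (ms^2) of ``window`` in a frequency ``band``.

    The window mean is removed and the band-passed reconstruction's mean
    square is returned; a pure in-band sinusoid of amplitude A gives ~A^2/2.
    """
    w = _as_spectral_window(window)
    if not (0 < band[0] < band[1] <= rate / 2):
        raise ValueError("band must lie within (0, Nyquist]")
    x = w - w.mean()
    return float(np.mean(band_filter(x, band, rate) ** 2))


def _as_spectral_window(window, n_expected: int = 512) -> np.ndarray:
    if isinstance(window, UniformSeries):
        window = window.values
    w = np.asarray(window, dtype=float)
    if w.shape[-1] != n_expected:
        raise ValueError(f"spectral window must have {n_expected} samples, got {w.shape[-1]}")
    return w


def _envelope_area(x: np.ndarray, dt: float) -> float:
    """Area between the upper and lower envelopes of ``x`` over its span.

    Envelopes are linear interpolations through the local maxima (resp.
    minima), held constant beyond the outermost extremum. A signal without
    interior extrema has zero envelope area.
    """
    n = x.size
    interior = np.arange(1, n - 1)
    is_max = (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:])
    is_min = (x[1:-1] <= x[:-2]) & (x[1:-1] < x[2:])
    imax = interior[is_max]
    imin = interior[is_min]
    if imax.size == 0 or imin.size == 0:
        return 0.0
    idx = np.arange(n)
    upper = np.interp(idx, imax, x[imax])
    lower = np.interp(idx, imin, x[imin])
    gap = np.clip(upper - lower, 0.0, None)
    return float(np.trapezoid(gap, dx=dt))


def ani(
    window,
    rate: float = 8.0,
    hf_band: tuple[float, float] = (0.15, 0.4),
    alpha: float = 5.1,
    beta: float = 1.2,
    divisor: float = 12.8,
) -> float:
    """Analgesia Nociception Index of a 64 s, 8 Hz tachogram window (0-100).

    The window is mean-centred and normalized to unit energy, band-pass
    filtered to the HF band with the same wavelet-packet filter used for the
    band energies, and the area between the upper and lower envelopes is
    measured on four 16 s sub-windows. The minimum area AUCmin is mapped to
    the score ``100 * (alpha * AUCmin + beta) / divisor``, clamped to
    [0, 100]. A zero-variance window has AUCmin = 0 and returns the floor
    score.
    """
    w = _as_spectral_window(window)
    u = w - w.mean()
    norm = np.sqrt(np.sum(u * u))
    if norm == 0.0:
        auc_min = 0.0
    else:
        filtered = band_filter(u / norm, hf_band, rate)
        quarter = w.size // 4
        dt = 1.0 / rate
        areas = [
            _envelope_area(filtered[k * quarter : (k + 1) * quarter], dt) for k in range(4)
        ]
        auc_min = min(areas)
    score = 100.0 * (alpha * auc_min + beta) / divisor
    return float(np.clip(score, 0.0, 100.0))


# ---------------------------------------------------------------------------
# sliding computation
# ---------------------------------------------------------------------------

def sliding_features(rr: RRSeries, spec: WindowSpec | None = None, **ani_kwargs) -> pd.DataFrame:
    """Compute all eight feature tracks on the 1 s slide grid.

    Returns a DataFrame indexed by grid time (s) with columns
    ``HR, ANI, STV, SDNN, LTV, RMSSD, LF, HF`` holding the trailing
    3-minute averages of the per-window values. Grid times where a feature's
    native window or its 3-minute history is incomplete hold NaN; rows where
    every feature is NaN are dropped.
    """
    spec = spec or WindowSpec()
    if spec.slide != 1.0:
        raise NotImplementedError("the slide grid is fixed at 1 s")
    t_first, t_last = rr.beat_times[0], rr.beat_times[-1]
    min_len = spec.average_len + max(spec.spectral_len, spec.stv_ltv_len) + 1.0
    if t_last - t_first < min_len:
        raise ValueError(
            f"recording of {t_last - t_first:.0f} s is too short "
            f"(needs at least ~{min_len:.0f} s)"
        )
    grid = np.arange(np.ceil(t_first), np.floor(t_last) + 1.0)

    raw = pd.DataFrame(index=pd.Index(grid, name="time_s"), columns=list(FEATURE_NAMES), dtype=float)
    _beat_window_tracks(rr, grid, spec, raw)
    _epoch_tracks(rr, grid, spec, raw)
    _spectral_tracks(rr, grid, spec, raw, ani_kwargs)

    window = int(round(spec.average_len / spec.slide))
    averaged = raw.rolling(window, min_periods=window).mean()
    return averaged.dropna(how="all")


def _beat_window_tracks(rr: RRSeries, grid, spec: WindowSpec, out: pd.DataFrame) -> None:
    """RMSSD, SDNN, HR over the trailing ``rmssd_sdnn_len`` beats, via prefix sums."""
    x = rr.intervals
    nbeats = spec.rmssd_sdnn_len
    # index of the last beat at or before each grid time
    last = np.searchsorted(rr.beat_times, grid, side="right") - 1
    ok = last >= nbeats - 1
    k = last[ok]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    d = np.diff(x)
    sd2 = np.concatenate([[0.0], np.cumsum(d * d)])

    tot = s1[k + 1] - s1[k + 1 - nbeats]
    tot2 = s2[k + 1] - s2[k + 1 - nbeats]
    mean = tot / nbeats
    var = np.clip((tot2 - nbeats * mean * mean) / (nbeats - 1), 0.0, None)
    # the window's 99 successive differences live at diff positions [k-99, k-1]
    dsum = sd2[k] - sd2[k + 1 - nbeats]

    out.loc[out.index[ok], "HR"] = 60000.0 / mean
    out.loc[out.index[ok], "SDNN"] = np.sqrt(var)
    out.loc[out.index[ok], "RMSSD"] = np.sqrt(dsum / (nbeats - 1))


def _epoch_tracks(rr: RRSeries, grid, spec: WindowSpec, out: pd.DataFrame) -> None:
    """STV and LTV from sixteen epoch means of the trailing 60 s at 4 Hz."""
    res = resample(rr, spec.resample_time_domain)
    nwin = spec.stv_ltv_samples            # 240
    nep = spec.n_epochs                    # 16
    eplen = nwin // nep                    # 15
    # last 4 Hz sample at or before each grid time
    j = np.floor((grid - res.start_time) * res.rate + 1e-9).astype(int)
    j = np.minimum(j, len(res) - 1)
    ok = j >= nwin - 1
    jj = j[ok]
    c = np.concatenate([[0.0], np.cumsum(res.values)])
    # epoch e of the window ending at jj spans samples [jj-239+15e, jj-239+15(e+1))
    starts = jj[:, None] - nwin + 1 + eplen * np.arange(nep)[None, :]
    means = (c[starts + eplen] - c[starts]) / eplen
    out.loc[out.index[ok], "STV"] = np.mean(np.abs(np.diff(means, axis=1)), axis=1)
    out.loc[out.index[ok], "LTV"] = means.max(axis=1) - means.min(axis=1)


def _spectral_tracks(rr: RRSeries, grid, spec: WindowSpec, out: pd.DataFrame, ani_kwargs) -> None:
    """LF, HF and ANI on trailing 64 s windows of the 8 Hz tachogram, batched."""
    res = resample(rr, spec.resample_spectral)
    nwin = spec.spectral_samples           # 512
    j = np.floor((grid - res.start_time) * res.rate + 1e-9).astype(int)
    j = np.minimum(j, len(res) - 1)
    ok = j >= nwin - 1
    if not ok.any():
        return
    jj = j[ok]
    windows = res.values[jj[:, None] - nwin + 1 + np.arange(nwin)[None, :]]
    centred = windows - windows.mean(axis=1, keepdims=True)

    rate = spec.resample_spectral
    nodes = _packet_decompose(centred)
    hf_rec = _packet_reconstruct(nodes, _band_leaf_weights(spec.hf_band, rate))
    lf_rec = _packet_reconstruct(nodes, _band_leaf_weights(spec.lf_band, rate))
    out.loc[out.index[ok], "LF"] = np.mean(lf_rec**2, axis=1)
    out.loc[out.index[ok], "HF"] = np.mean(hf_rec**2, axis=1)

    # ANI: unit-energy normalization, HF-band reconstruction, envelope areas.
    # The packet filter is linear, so the HF reconstruction scales with 1/norm.
    norms = np.sqrt(np.sum(centred * centred, axis=1, keepdims=True))
    safe = np.where(norms == 0.0, 1.0, norms)
    filtered = hf_rec / safe
    alpha = ani_kwargs.get("alpha", 5.1)
    beta = ani_kwargs.get("beta", 1.2)
    divisor = ani_kwargs.get("divisor", 12.8)
    quarter = nwin // 4
    dt = 1.0 / rate
    scores = np.empty(len(jj))
    for i in range(len(jj)):
        if norms[i, 0] == 0.0:
            auc_min = 0.0
        else:
            row = filtered[i]
            auc_min = min(
                _envelope_area(row[k * quarter : (k + 1) * quarter], dt) for k in range(4)
            )
        scores[i] = np.clip(100.0 * (alpha * auc_min + beta) / divisor, 0.0, 100.0)
    out.loc[out.index[ok], "ANI"] = scores


def brute_force_features(
    rr: RRSeries, time: float, spec: WindowSpec | None = None
) -> dict[str, float]:
    """Single-time recomputation of all raw (pre-averaging) features.

    Independent of the vectorized path: extracts each native window directly
    and applies the scalar operators. Returns NaN for features whose window
    is incomplete at ``time``.
    """
    spec = spec or WindowSpec()
    vals: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}

    last = int(np.searchsorted(rr.beat_times, time, side="right")) - 1
    if last >= spec.rmssd_sdnn_len - 1:
        w = rr.intervals[last - spec.rmssd_sdnn_len + 1 : last + 1]
        vals["HR"] = heart_rate(w)
        vals["SDNN"] = sdnn(w)
        vals["RMSSD"] = rmssd(w)

    res4 = resample(rr, spec.resample_time_domain)
    j = int(np.floor((time - res4.start_time) * res4.rate + 1e-9))
    j = min(j, len(res4) - 1)
    if j >= spec.stv_ltv_samples - 1:
        w = res4.values[j - spec.stv_ltv_samples + 1 : j + 1]
        m = epoch_means(w, spec.n_epochs)
        vals["STV"] = stv(m)
        vals["LTV"] = ltv(m)

    res8 = resample(rr, spec.resample_spectral)
    j = int(np.floor((time - res8.start_time) * res8.rate + 1e-9))
    j = min(j, len(res8) - 1)
    if j >= spec.spectral_samples - 1:
        w = res8.values[j - spec.spectral_samples + 1 : j + 1]
        vals["LF"] = wavelet_band_energy(w, spec.lf_band, spec.resample_spectral)
        vals["HF"] = wavelet_band_energy(w, spec.hf_band, spec.resample_spectral)
        vals["ANI"] = ani(w, spec.resample_spectral, spec.hf_band)
    return vals
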
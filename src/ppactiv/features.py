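"""Physiological feature extraction on a 1 Hz grid.

Eleven features summarise four signal families over trailing windows:

* heart rate variability from the beat stream — mHR (beats/min), mRRi
  (mean RR, ms), SDNN (sample standard deviation of RR, ms), RMSSD
  (root-mean-square of successive RR differences, ms), all over a
  5-minute trailing window;
* electrodermal activity — mAmp (mean skin conductance, μS), Slope
  (mean absolute first difference, rate-normalised to μS/s), Events
  (count of skin-conductance responses, i.e. rises of more than
  0.05 μS in under 5 s);
* blood volume pulse — mean absolute value, minimum, maximum;
* skin temperature — trailing least-squares slope (°C/s) as the
  operationalisation of the instantaneous rate of change.

Every feature at time ``t`` uses only samples in ``(t - window, t]``:
features are strictly causal.  Rows whose windows are not yet fully
populated are masked invalid rather than filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RangeError
from .io_formats import ChannelSeries, IBISeries, PhysioRecording

#: Fixed feature order of the observation vector y_t.
FEATURE_NAMES = (
    "mHR", "mRRi", "SDNN", "RMSSD",
    "mAmp", "Slope", "Events",
    "BVPmeanAbs", "BVPmin", "BVPmax",
    "TEMPslope",
)

#: Column indices of each signal family within FEATURE_NAMES.
FAMILY_COLUMNS = {
    "hrv": (0, 1, 2, 3),
    "eda": (4, 5, 6),
    "bvp": (7, 8, 9),
    "temp": (10,),
}

# tolerance used to decide whether two beats are truly consecutive
# (a larger gap than the recorded RR implies dropped beats in between)
_SUCCESSIVE_TOL_S = 1e-6


@dataclass(frozen=True)
class FeatureConfig:
    """Window lengths and skin-conductance-response detection constants."""

    hrv_window_s: float = 300.0
    eda_window_s: float = 300.0
    bvp_window_s: float = 300.0
    temp_slope_window_s: float = 60.0
    scr_rise_threshold_us: float = 0.05
    scr_rise_max_s: float = 5.0


@dataclass
class FeatureSeries:
    """1 Hz matrix of the 11 features with a per-row validity mask."""

    trader_id: str
    day: str
    timestamps: np.ndarray
    matrix: np.ndarray
    valid: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n(self) -> int:
        return int(self.timestamps.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df.insert(0, "timestamp", self.timestamps)
        df["valid"] = self.valid.astype(int)
        return df


# ---------------------------------------------------------------------------
# scalar operations (reference semantics; the assembler vectorises the same
# definitions)
# ---------------------------------------------------------------------------

def _window_mask(times: np.ndarray, t: float, window_s: float) -> np.ndarray:
    return (times > t - window_s) & (times <= t)


def hrv_features(
    ibi: IBISeries, t: float, window_s: float = 300.0
) -> tuple[float, float, float, float]:
    """(mHR, mRRi, SDNN, RMSSD) over beats in ``(t - window_s, t]``.

    With fewer than two beats all four are NaN; with exactly two, RMSSD
    alone is NaN.  RMSSD uses only successive beat pairs — pairs whose
    inter-beat gap equals the recorded RR, so runs of dropped beats do
    not fabricate large differences.
    """
    times = ibi.times
    sel = _window_mask(times, t, window_s)
    rr_ms = ibi.rr[sel] * 1000.0
    n = rr_ms.size
    if n < 2:
        return (math.nan,) * 4
    mrri = float(np.mean(rr_ms))
    mhr = 60000.0 / mrri
    sdnn = float(np.std(rr_ms, ddof=1))
    if n < 3:
        return mhr, mrri, sdnn, math.nan
    idx = np.flatnonzero(sel)
    gaps = np.diff(ibi.offsets[idx])
    succ = np.abs(gaps - ibi.rr[idx[1:]]) <= _SUCCESSIVE_TOL_S
    diffs = np.diff(rr_ms)[succ]
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else math.nan
    return mhr, mrri, sdnn, rmssd


def detect_scr_events(
    eda: ChannelSeries,
    span: tuple[float, float] | None = None,
    rise_threshold_us: float = 0.05,
    rise_max_s: float = 5.0,
) -> list[tuple[float, float, float]]:
    """Detect skin-conductance responses as qualifying strictly-rising runs.

    A maximal strictly-rising run of the EDA signal yields one event when
    some sub-segment shorter than ``rise_max_s`` rises by more than
    ``rise_threshold_us``; overlapping qualifying sub-segments of one run
    are merged.  Returns ``(onset_time, peak_time, amplitude_us)`` per
    event in epoch seconds, where the amplitude is the run's total rise.
    """
    times = eda.times
    x = eda.values
    if span is not None:
        a, b = span
        if a < times[0] - 1e-9 or b > eda.end_time + 1e-9:
            raise RangeError(
                f"span ({a}, {b}) outside EDA channel "
                f"[{times[0]}, {eda.end_time}]"
            )
        sel = (times >= a) & (times <= b)
        times, x = times[sel], x[sel]
    if x.size < 2:
        return []
    rising = np.diff(x) > 0
    # boundaries of maximal strictly-rising runs
    edges = np.flatnonzero(np.diff(rising.astype(np.int8)))
    starts = [0] if rising[0] else []
    starts += [e + 1 for e in edges if rising[e + 1]]
    ends = [e + 1 for e in edges if rising[e]]
    if rising[-1]:
        ends.append(x.size - 1)
    # max samples spanning strictly less than rise_max_s
    wmax = int(np.ceil(rise_max_s * eda.rate_hz)) - 1
    wmax = max(wmax, 1)
    events = []
    for s, e in zip(starts, ends):
        seg = x[s : e + 1]
        k = np.arange(seg.size)
        hi = np.minimum(k + wmax, seg.size - 1)
        if np.any(seg[hi] - seg > rise_threshold_us):
            events.append((float(times[s]), float(times[e]), float(seg[-1] - seg[0])))
    return events


def eda_features(
    eda: ChannelSeries,
    t: float,
    window_s: float = 300.0,
    events: list[tuple[float, float, float]] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[float, float, float]:
    """(mAmp, Slope, Events) over EDA samples in ``(t - window_s, t]``.

    ``events`` may carry pre-computed SCR detections for the whole
    channel; otherwise they are detected on the fly.  Slope is the mean
    absolute first difference multiplied by the sampling rate, i.e. a
    rate of change in μS/s, so it is invariant to the device's sampling
    rate.
    """
    times = eda.times
    sel = _window_mask(times, t, window_s)
    x = eda.values[sel]
    fin = np.isfinite(x)
    pair_ok = fin[:-1] & fin[1:] if x.size >= 2 else np.zeros(0, dtype=bool)
    if fin.sum() < 2 or not pair_ok.any():
        return (math.nan,) * 3
    mamp = float(np.mean(x[fin]))
    slope = float(np.mean(np.abs(np.diff(x))[pair_ok])) * eda.rate_hz
    if events is None:
        events = detect_scr_events(
            eda,
            rise_threshold_us=config.scr_rise_threshold_us,
            rise_max_s=config.scr_rise_max_s,
        )
    n_events = sum(1 for _, peak, _ in events if t - window_s < peak <= t)
    return mamp, slope, float(n_events)


def bvp_features(
    bvp: ChannelSeries, t: float, window_s: float = 300.0
) -> tuple[float, float, float]:
    """(mean |BVP|, min BVP, max BVP) over samples in ``(t - window_s, t]``."""
    x = bvp.values[_window_mask(bvp.times, t, window_s)]
    if x.size == 0 or np.isnan(x).all():
        return (math.nan,) * 3
    return (
        float(np.nanmean(np.abs(x))),
        float(np.nanmin(x)),
        float(np.nanmax(x)),
    )


def temp_slope(
    temp: ChannelSeries, t: float, slope_window_s: float = 60.0
) -> float:
    """Trailing least-squares slope of skin temperature in °C/s."""
    sel = _window_mask(temp.times, t, slope_window_s)
    x = temp.values[sel]
    tt = temp.times[sel]
    ok = np.isfinite(x)
    if ok.sum() < 2:
        return math.nan
    tt, x = tt[ok], x[ok]
    tc = tt - tt.mean()
    denom = float(np.sum(tc**2))
    if denom == 0.0:
        return math.nan
    return float(np.sum(tc * (x - x.mean())) / denom)


# ---------------------------------------------------------------------------
# vectorised assembly
# ---------------------------------------------------------------------------

def _second_grid(session_span: tuple[float, float]) -> np.ndarray:
    """Integer epoch seconds t with span_start < t <= span_end."""
    t0, t1 = session_span
    return np.arange(math.floor(t0) + 1, math.floor(t1) + 1, dtype=np.int64)


def _bounds(times: np.ndarray, grid: np.ndarray, window_s: float):
    lo = np.searchsorted(times, grid - window_s, side="right")
    hi = np.searchsorted(times, grid, side="right")
    return lo, hi


def _csum(x: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(x)])


def _hrv_block(ibi: IBISeries, grid: np.ndarray, window_s: float) -> np.ndarray:
    out = np.full((grid.size, 4), np.nan)
    if ibi.n == 0:
        return out
    times = ibi.times
    rr_ms = ibi.rr * 1000.0
    lo, hi = _bounds(times, grid, window_s)
    cnt = hi - lo
    center = rr_ms.mean()
    c = rr_ms - center
    s1, s2 = _csum(c), _csum(c * c)
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = (s1[hi] - s1[lo]) / cnt
        mrri = mc + center
        var = (s2[hi] - s2[lo] - cnt * mc**2) / (cnt - 1)
        sdnn = np.sqrt(np.clip(var, 0.0, None))
        mhr = 60000.0 / mrri
    ok2 = cnt >= 2
    out[ok2, 0] = mhr[ok2]
    out[ok2, 1] = mrri[ok2]
    out[ok2, 2] = sdnn[ok2]
    # successive-difference pairs: pair j couples beats j and j+1
    if ibi.n >= 2:
        gaps = np.diff(ibi.offsets)
        succ = np.abs(gaps - ibi.rr[1:]) <= _SUCCESSIVE_TOL_S
        d2 = np.diff(rr_ms) ** 2
        p2 = _csum(np.where(succ, d2, 0.0))
        pc = _csum(succ.astype(float))
        jlo = lo  # first pair fully inside: beats lo, lo+1 -> pair lo
        jhi = np.maximum(hi - 1, jlo)  # pairs lo .. hi-2
        npairs = pc[jhi] - pc[jlo]
        with np.errstate(invalid="ignore", divide="ignore"):
            rmssd = np.sqrt((p2[jhi] - p2[jlo]) / npairs)
        ok3 = (cnt >= 3) & (npairs >= 1)
        out[ok3, 3] = rmssd[ok3]
    return out


def _eda_block(
    eda: ChannelSeries, grid: np.ndarray, window_s: float, config: FeatureConfig
) -> np.ndarray:
    out = np.full((grid.size, 3), np.nan)
    times = eda.times
    x = eda.values
    fin = np.isfinite(x)
    x0 = np.where(fin, x, 0.0)
    lo, hi = _bounds(times, grid, window_s)
    s1, sn = _csum(x0), _csum(fin)
    nfin = sn[hi] - sn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mamp = (s1[hi] - s1[lo]) / nfin
    # absolute first differences over pairs whose two samples are both finite
    if x.size >= 2:
        pair_ok = fin[:-1] & fin[1:]
        ad = np.where(pair_ok, np.abs(np.diff(x0)), 0.0)
    else:
        pair_ok = np.zeros(0, dtype=bool)
        ad = np.zeros(0)
    sd, sp = _csum(ad), _csum(pair_ok)
    jlo = lo
    jhi = np.maximum(hi - 1, jlo)  # pairs lo .. hi-2 lie fully in the window
    npairs = sp[jhi] - sp[jlo]
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (sd[jhi] - sd[jlo]) / npairs * eda.rate_hz
    events = detect_scr_events(
        eda,
        rise_threshold_us=config.scr_rise_threshold_us,
        rise_max_s=config.scr_rise_max_s,
    )
    peaks = np.array(sorted(p for _, p, _ in events))
    elo = np.searchsorted(peaks, grid - window_s, side="right")
    ehi = np.searchsorted(peaks, grid, side="right")
    ok = (nfin >= 2) & (npairs >= 1)
    out[ok, 0] = mamp[ok]
    out[ok, 1] = slope[ok]
    out[ok, 2] = (ehi - elo)[ok]
    return out


def _bvp_block(bvp: ChannelSeries, grid: np.ndarray, window_s: float) -> np.ndarray:
    out = np.full((grid.size, 3), np.nan)
    times = bvp.times
    x = bvp.values
    fin = np.isfinite(x)
    lo, hi = _bounds(times, grid, window_s)
    cnt = hi - lo
    s_abs, sn = _csum(np.where(fin, np.abs(x), 0.0)), _csum(fin)
    nfin = sn[hi] - sn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_abs = (s_abs[hi] - s_abs[lo]) / nfin
    w0 = int(round(window_s * bvp.rate_hz))
    s = pd.Series(x)
    rmin = s.rolling(w0, min_periods=1).min().to_numpy()
    rmax = s.rolling(w0, min_periods=1).max().to_numpy()
    full = (cnt == w0) & (nfin >= 1) & (hi >= 1)
    out[full, 0] = mean_abs[full]
    out[full, 1] = rmin[hi[full] - 1]
    out[full, 2] = rmax[hi[full] - 1]
    return out


def _temp_block(temp: ChannelSeries, grid: np.ndarray, window_s: float) -> np.ndarray:
    out = np.full((grid.size, 1), np.nan)
    x = temp.values
    times = temp.times
    fin = np.isfinite(x)
    center = float(np.nanmean(x)) if fin.any() else 0.0
    c = np.where(fin, x - center, 0.0)
    k = np.arange(x.size, dtype=float) - x.size / 2.0  # centred sample index
    lo, hi = _bounds(times, grid, window_s)
    sn = _csum(fin)
    s1 = _csum(c)
    sk = _csum(np.where(fin, k, 0.0))
    sk2 = _csum(np.where(fin, k * k, 0.0))
    skx = _csum(k * c)
    n = sn[hi] - sn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (skx[hi] - skx[lo]) - (sk[hi] - sk[lo]) * (s1[hi] - s1[lo]) / n
        den = (sk2[hi] - sk2[lo]) - (sk[hi] - sk[lo]) ** 2 / n
        slope = num / den * temp.rate_hz  # per-sample -> per-second
    ok = (n >= 2) & (den > 0)
    out[ok, 0] = slope[ok]
    return out


def assemble_feature_series(
    rec: PhysioRecording, config: FeatureConfig = FeatureConfig()
) -> FeatureSeries:
    """Evaluate all 11 features at 1 Hz over the recording's session span.

    A row is valid only when every feature is computable and every
    family's trailing window is fully inside the session; no imputation
    is performed.
    """
    for name in ("EDA", "BVP", "TEMP"):
        if name not in rec.channels:
            raise ConfigurationError(f"required channel {name!r} missing "
                                     f"from recording {rec.trader_id}/{rec.day}")
    if rec.ibi.n == 0:
        raise ConfigurationError(
            f"recording {rec.trader_id}/{rec.day} has an empty IBI stream"
        )
    grid = _second_grid(rec.session_span)
    blocks = [
        _hrv_block(rec.ibi, grid, config.hrv_window_s),
        _eda_block(rec.channels["EDA"], grid, config.eda_window_s, config),
        _bvp_block(rec.channels["BVP"], grid, config.bvp_window_s),
        _temp_block(rec.channels["TEMP"], grid, config.temp_slope_window_s),
    ]
    matrix = np.hstack(blocks)
    warmup = grid - rec.session_span[0] >= max(
        config.hrv_window_s, config.eda_window_s, config.bvp_window_s,
        config.temp_slope_window_s,
    )
    valid = np.isfinite(matrix).all(axis=1) & warmup
    return FeatureSeries(
        trader_id=rec.trader_id,
        day=rec.day,
        timestamps=grid,
        matrix=matrix,
        valid=valid,
    )
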
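"""Psychophysiological (PP) activation from the feature matrix.

Activation at time ``t`` is the squared Mahalanobis distance of the
feature vector ``y_t`` from its own expanding history,

    d_M(y_t) = (y_t - mu_t)' Sigma_t^{-1} (y_t - mu_t),

where ``mu_t`` and ``Sigma_t`` are the sample mean and covariance of the
valid rows ``y_1 .. y_t`` of the same trading day.  The expanding window
makes the score strictly causal: no sample after ``t`` enters the
baseline, so there is no look-ahead bias.  Under stationarity with
``d`` features, d_M is asymptotically chi-squared with ``d`` degrees of
freedom, which makes its day-level mean interpretable (about ``d``).

Days are labelled *mildly activated* where d_M exceeds the day mean by
1.5 day standard deviations and *extremely activated* above 3; episodes
are maximal contiguous runs above a threshold.  Three aggregates
summarise a trader-day: average activation, mild/extreme activation
proportion, and activation length (mean mild-episode duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySeriesError, NumericalError
from .features import FAMILY_COLUMNS, FEATURE_NAMES, FeatureSeries

#: mild / extreme thresholds in day-standard-deviation units
DEFAULT_THRESHOLDS = (1.5, 3.0)

ACTIVATION_MODES = ("overall",) + tuple(FAMILY_COLUMNS)


@dataclass(frozen=True)
class ActivationConfig:
    """Burn-in and regularisation for the expanding-moment score.

    ``ridge`` scales the mean diagonal of Sigma_t before inversion; it
    guards against early-day degeneracy (the integer SCR-count feature
    is often constant at first).  Burn-in requires both ``burn_in_s``
    seconds of history and ``min_history_mult * d`` valid rows.
    """

    ridge: float = 1e-6
    burn_in_s: float = 300.0
    min_history_mult: int = 5
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS


@dataclass
class ActivationSeries:
    """1 Hz activation values with day statistics and z-scores."""

    trader_id: str
    day: str
    timestamps: np.ndarray
    dm: np.ndarray
    valid: np.ndarray
    day_mean: float
    day_std: float
    z: np.ndarray
    mode: str = "overall"

    @property
    def n(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class ActivationEpisode:
    """A maximal contiguous run of supra-threshold 1 Hz samples."""

    start: int
    end: int
    level: str  # "mild" | "extreme"

    @property
    def duration_s(self) -> float:
        return float(self.end - self.start + 1)  # inclusive 1 Hz grid


@dataclass
class ActivationSummary:
    """Per-trader-day aggregates of the activation series."""

    trader_id: str
    day: str
    average_activation: float
    mild_proportion: float
    extreme_proportion: float
    activation_length_s: float

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationSummary":
        return cls(**d)


@dataclass
class HistogramSet:
    """Cohort histograms plus a min/max/mean/std table per metric."""

    metrics: dict[str, dict]

    @classmethod
    def from_dict(cls, d: dict) -> "HistogramSet":
        return cls(**d)


# ---------------------------------------------------------------------------
# moments and the quadratic form
# ---------------------------------------------------------------------------

def expanding_moments(
    features: FeatureSeries, t: float, columns: tuple[int, ...] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and covariance (ddof 1) of valid rows up to and including t.

    Strictly causal: rows after ``t`` never enter.  Raises on fewer than
    two valid rows of history.
    """
    sel = features.valid & (features.timestamps <= t)
    X = features.matrix[sel]
    if columns is not None:
        X = X[:, list(columns)]
    if X.shape[0] < 2:
        raise EmptySeriesError(
            f"need >= 2 valid rows up to t={t}, have {X.shape[0]}"
        )
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    return mu, np.atleast_2d(sigma)


def mahalanobis_activation(
    y: np.ndarray, mu: np.ndarray, sigma: np.ndarray, ridge: float = 1e-6
) -> float:
    """Squared Mahalanobis distance with a relative ridge regulariser.

    The covariance is inverted after adding ``ridge * mean(diag(sigma))``
    to the diagonal.  A zero residual scores 0 even when the covariance
    is degenerate (a constant history).
    """
    y = np.asarray(y, float)
    r = y - np.asarray(mu, float)
    sigma = np.atleast_2d(np.asarray(sigma, float))
    if not np.any(r):
        return 0.0
    lam = ridge * float(np.mean(np.diag(sigma)))
    A = sigma + lam * np.eye(sigma.shape[0])
    try:
        u = np.linalg.solve(A, r)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "covariance singular after regularisation "
            f"(cond={np.linalg.cond(sigma):.3e})"
        ) from exc
    return float(max(r @ u, 0.0))


def _mode_columns(mode: str, n_cols: int) -> tuple[int, ...]:
    if mode == "overall":
        return tuple(range(n_cols))
    if mode in FAMILY_COLUMNS:
        return FAMILY_COLUMNS[mode]
    raise ValueError(f"unknown activation mode {mode!r}; "
                     f"expected one of {ACTIVATION_MODES}")


def activation_series(
    features: FeatureSeries,
    mode: str = "overall",
    config: ActivationConfig = ActivationConfig(),
) -> ActivationSeries:
    """Score every valid row against its expanding history.

    Implemented with centred prefix sums and one batched linear solve,
    which reproduces the per-row brute-force recomputation to ~1e-10.
    Day mean/std (ddof 1) are taken over the valid scores of the whole
    day, and z-scores attached.
    """
    cols = _mode_columns(mode, features.matrix.shape[1])
    d = len(cols)
    vidx = np.flatnonzero(features.valid)
    if vidx.size == 0:
        raise EmptySeriesError(
            f"no valid feature rows for {features.trader_id}/{features.day}"
        )
    X = features.matrix[np.ix_(vidx, list(cols))]
    m = X.shape[0]
    center = X.mean(axis=0)
    C = X - center  # numerical centring only; dM is shift invariant
    k = np.arange(1, m + 1, dtype=float)
    S1 = np.cumsum(C, axis=0)
    S2 = np.cumsum(C[:, :, None] * C[:, None, :], axis=0)
    mu = S1 / k[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = (S2 - k[:, None, None] * mu[:, None, :] * mu[:, :, None]) / (
            k - 1.0
        )[:, None, None]
    resid = C - mu

    # burn-in: enough elapsed time and enough accumulated valid rows
    t_valid = features.timestamps[vidx]
    ok = (k >= config.min_history_mult * d) & (
        t_valid - t_valid[0] >= config.burn_in_s
    ) & (k >= d + 1)

    dm_valid = np.full(m, np.nan)
    idx = np.flatnonzero(ok)
    if idx.size:
        sig = sigma[idx]
        diag_mean = np.einsum("kii->k", sig) / d
        lam = config.ridge * diag_mean
        A = sig + lam[:, None, None] * np.eye(d)
        r = resid[idx]
        zero_r = ~np.any(r, axis=1)
        solve_rows = np.flatnonzero(~zero_r)
        vals = np.zeros(idx.size)
        if solve_rows.size:
            try:
                u = np.linalg.solve(A[solve_rows], r[solve_rows][:, :, None])
                vals[solve_rows] = np.einsum(
                    "ki,ki->k", r[solve_rows], u[:, :, 0]
                )
            except np.linalg.LinAlgError:
                for j in solve_rows:
                    vals[j] = mahalanobis_activation(
                        X[idx[j]], mu[idx[j]] + center, sigma[idx[j]],
                        ridge=config.ridge,
                    )
        dm_valid[idx] = np.clip(vals, 0.0, None)

    n = features.n
    dm = np.full(n, np.nan)
    dm[vidx] = dm_valid
    valid = np.zeros(n, dtype=bool)
    valid[vidx[ok]] = True

    scores = dm[valid]
    if scores.size == 0:
        raise EmptySeriesError(
            f"no post-burn-in rows for {features.trader_id}/{features.day}"
        )
    day_mean = float(np.mean(scores))
    day_std = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    z = np.full(n, np.nan)
    if day_std > 0:
        z[valid] = (scores - day_mean) / day_std
    else:
        z[valid] = 0.0
    return ActivationSeries(
        trader_id=features.trader_id,
        day=features.day,
        timestamps=features.timestamps,
        dm=dm,
        valid=valid,
        day_mean=day_mean,
        day_std=day_std,
        z=z,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# episodes and aggregates
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start_index, end_index) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def label_episodes(
    act: ActivationSeries,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[ActivationEpisode]:
    """Maximal supra-threshold runs at the mild and extreme levels.

    A run is broken by invalid samples as well as by sub-threshold
    samples; no gap merging is applied.  A zero-variance day yields no
    episodes.  Because the extreme threshold exceeds the mild one, every
    extreme sample lies inside a mild episode.
    """
    mild_thr, extreme_thr = sorted(thresholds)
    if act.day_std == 0:
        return []
    episodes: list[ActivationEpisode] = []
    for level, thr in (("mild", mild_thr), ("extreme", extreme_thr)):
        cut = act.day_mean + thr * act.day_std
        mask = act.valid & np.nan_to_num(act.dm > cut, nan=False)
        for s, e in _runs(mask):
            episodes.append(
                ActivationEpisode(
                    start=int(act.timestamps[s]),
                    end=int(act.timestamps[e]),
                    level=level,
                )
            )
    return episodes


def summarize_day(
    act: ActivationSeries, episodes: list[ActivationEpisode]
) -> ActivationSummary:
    """Average activation, mild/extreme proportions (%), activation length (s).

    The mild proportion counts every sample above the mild threshold and
    is therefore inclusive of extreme samples; activation length is the
    mean duration of mild episodes (0 when there are none).
    """
    scores = act.dm[act.valid]
    if scores.size == 0:
        raise EmptySeriesError("no valid activation samples to summarise")
    n_valid = scores.size
    mild_runs = [e for e in episodes if e.level == "mild"]
    extreme_runs = [e for e in episodes if e.level == "extreme"]
    mild_n = sum(e.duration_s for e in mild_runs)
    extreme_n = sum(e.duration_s for e in extreme_runs)
    lengths = [e.duration_s for e in mild_runs]
    return ActivationSummary(
        trader_id=act.trader_id,
        day=act.day,
        average_activation=float(np.mean(scores)),
        mild_proportion=100.0 * mild_n / n_valid,
        extreme_proportion=100.0 * extreme_n / n_valid,
        activation_length_s=float(np.mean(lengths)) if lengths else 0.0,
    )


_METRIC_FIELDS = (
    "average_activation",
    "mild_proportion",
    "extreme_proportion",
    "activation_length_s",
)


def cohort_histograms(
    summaries: list[ActivationSummary], bins: int = 20
) -> HistogramSet:
    """Histogram counts plus min/max/mean/std per activation metric."""
    if not summaries:
        raise EmptySeriesError("no summaries to histogram")
    metrics: dict[str, dict] = {}
    for name in _METRIC_FIELDS:
        vals = np.array([getattr(s, name) for s in summaries], dtype=float)
        counts, edges = np.histogram(vals, bins=bins)
        metrics[name] = {
            "counts": counts.tolist(),
            "bin_edges": edges.tolist(),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return HistogramSet(metrics=metrics)
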
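"""Granger-causality of market fluctuations on trader activation.

For each trader-day and market index, the 1 Hz activation series is
averaged to minutes, both series are first-differenced to remove
non-stationarity, and the null "market changes do not Granger-cause
activation changes" is tested with the sum-of-squared-residuals (SSR)
chi-squared statistic at a fixed lag order (default 10 minutes):

    chi2 = n_eff * (SSR_restricted - SSR_unrestricted) / SSR_unrestricted

with ``lag_order`` degrees of freedom, where the restricted model
regresses the activation change on its own lags and the unrestricted
model adds the market-change lags.  Across traders the tests for one
index form a family and are corrected with the Holm-Bonferroni
step-down procedure at level 0.05.  A one-sample Kolmogorov-Smirnov
statistic against the uniform distribution diagnoses whether a family's
p-values depart from the global null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import kolmogorov
from scipy.stats import chi2 as chi2_dist

from .activation import ActivationSeries
from .errors import DegenerateDesignError, ValidationError
from .io_formats import MarketSeries

logger = logging.getLogger(__name__)

DEFAULT_LAG_ORDER = 10
DEFAULT_ALPHA = 0.05


@dataclass
class GrangerResult:
    """Outcome of one SSR chi-squared Granger test."""

    trader_id: str
    day: str
    index_name: str
    lag_order: int
    statistic: float
    df: int
    p_value: float
    n_obs: int

    @classmethod
    def from_dict(cls, d: dict) -> "GrangerResult":
        return cls(**d)


@dataclass
class GrangerScanResult:
    """All pairwise tests plus per-index corrections and diagnostics."""

    results: list[GrangerResult]
    reject: list[bool]
    per_index_significant: dict[str, int]
    per_index_ks: dict[str, dict]
    alpha: float
    skipped: list[dict] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "GrangerScanResult":
        d = dict(d)
        d["results"] = [GrangerResult.from_dict(r) for r in d["results"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# series preparation
# ---------------------------------------------------------------------------

def minute_average(act: ActivationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Mean valid activation per calendar minute (floor(epoch / 60)).

    Minutes not fully covered by the 1 Hz grid (partial leading or
    trailing minutes) and minutes without any valid sample are dropped.
    Returns (minute indices, means).
    """
    mins = act.timestamps // 60
    uniq, inverse, counts = np.unique(mins, return_inverse=True,
                                      return_counts=True)
    vsum = np.bincount(inverse, weights=np.where(act.valid, act.dm, 0.0),
                       minlength=uniq.size)
    vcnt = np.bincount(inverse, weights=act.valid.astype(float),
                       minlength=uniq.size)
    keep = (counts == 60) & (vcnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = vsum / vcnt
    return uniq[keep].astype(np.int64), means[keep]


def prepare_pair(
    act: ActivationSeries, mkt: MarketSeries, min_overlap_min: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned first differences of minute activation and the market index.

    Both series are restricted to common calendar minutes; differences
    are taken only between consecutive minutes.
    """
    y_min, y_val = minute_average(act)
    m_min = (mkt.timestamps // 60).astype(np.int64)
    m_uniq, m_first = np.unique(m_min, return_index=True)
    common, yi, mi = np.intersect1d(y_min, m_uniq, return_indices=True)
    if common.size < min_overlap_min:
        raise ValidationError(
            f"only {common.size} overlapping minutes between activation "
            f"and {mkt.index_name}; need >= {min_overlap_min}"
        )
    y = y_val[yi]
    m = mkt.values[m_first[mi]]
    consec = np.diff(common) == 1
    dy = np.diff(y)[consec]
    dm = np.diff(m)[consec]
    return dy, dm


# ---------------------------------------------------------------------------
# the SSR chi-squared test
# ---------------------------------------------------------------------------

def _lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """Columns x_{t-1} .. x_{t-p} for t = p .. n-1."""
    n = x.size
    return np.column_stack([x[p - j : n - j] for j in range(1, p + 1)])


def granger_ssr_test(
    dy: np.ndarray,
    dm: np.ndarray,
    lag_order: int = DEFAULT_LAG_ORDER,
    trader_id: str = "",
    day: str = "",
    index_name: str = "",
) -> GrangerResult:
    """SSR chi-squared test that ``dm`` Granger-causes ``dy``.

    Restricted OLS: dy_t on a constant and its own lags 1..p.
    Unrestricted: plus lags 1..p of dm.  Requires at least
    ``3 * lag_order`` usable rows after lag embedding and a
    full-rank unrestricted design.
    """
    dy = np.asarray(dy, float)
    dm = np.asarray(dm, float)
    if dy.shape != dm.shape or dy.ndim != 1:
        raise ValidationError("dy and dm must be matching 1-d arrays")
    p = int(lag_order)
    n_eff = dy.size - p
    if n_eff < 3 * p:
        raise ValidationError(
            f"need >= {3 * p} rows after embedding, have {n_eff}"
        )
    target = dy[p:]
    const = np.ones((n_eff, 1))
    X_r = np.hstack([const, _lag_matrix(dy, p)])
    X_u = np.hstack([X_r, _lag_matrix(dm, p)])
    rank_u = np.linalg.matrix_rank(X_u)
    if rank_u < X_u.shape[1]:
        raise DegenerateDesignError(
            f"unrestricted design rank {rank_u} < {X_u.shape[1]} "
            "(constant or collinear regressor block)"
        )
    beta_r, *_ = np.linalg.lstsq(X_r, target, rcond=None)
    beta_u, *_ = np.linalg.lstsq(X_u, target, rcond=None)
    ssr_r = float(np.sum((target - X_r @ beta_r) ** 2))
    ssr_u = float(np.sum((target - X_u @ beta_u) ** 2))
    if ssr_u <= 0:
        raise DegenerateDesignError("unrestricted SSR is zero")
    stat = n_eff * (ssr_r - ssr_u) / ssr_u
    stat = max(stat, 0.0)
    p_value = float(chi2_dist.sf(stat, p))
    return GrangerResult(
        trader_id=trader_id,
        day=day,
        index_name=index_name,
        lag_order=p,
        statistic=stat,
        df=p,
        p_value=p_value,
        n_obs=int(n_eff),
    )


# ---------------------------------------------------------------------------
# multiplicity and diagnostics
# ---------------------------------------------------------------------------

def holm_bonferroni(p_values, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Step-down Holm-Bonferroni rejections in the input order.

    Sort ascending and reject p_(k) while p_(k) <= alpha / (m - k + 1),
    stopping at the first failure.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, i in enumerate(order):  # k = 0 .. m-1
        if p[i] <= alpha / (m - k):
            reject[i] = True
        else:
            break
    return reject


def ks_uniformity(p_values) -> tuple[float, float]:
    """One-sample KS statistic of p-values against Uniform[0, 1].

    D = sup_x |F_n(x) - x|; the p-value uses the asymptotic Kolmogorov
    distribution of sqrt(n) * D.
    """
    p = np.sort(np.asarray(p_values, float))
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    k = np.arange(1, n + 1)
    d_plus = np.max(k / n - p)
    d_minus = np.max(p - (k - 1) / n)
    D = float(max(d_plus, d_minus))
    return D, float(kolmogorov(np.sqrt(n) * D))


def causality_scan(
    acts: list[ActivationSeries],
    mkts: list[MarketSeries],
    lag_order: int = DEFAULT_LAG_ORDER,
    alpha: float = DEFAULT_ALPHA,
) -> GrangerScanResult:
    """Test every (trader-day, index) pair and correct within each index.

    Pairs that cannot be tested (insufficient overlap, degenerate
    designs) are skipped with a recorded reason, never fatally.  The
    Holm-Bonferroni family is all trader-day tests of one index.
    """
    results: list[GrangerResult] = []
    skipped: list[dict] = []
    for mkt in mkts:
        for act in acts:
            try:
                dy, dm = prepare_pair(act, mkt)
                res = granger_ssr_test(
                    dy, dm, lag_order=lag_order,
                    trader_id=act.trader_id, day=act.day,
                    index_name=mkt.index_name,
                )
                results.append(res)
            except (ValidationError, DegenerateDesignError) as exc:
                skipped.append({
                    "trader_id": act.trader_id, "day": act.day,
                    "index_name": mkt.index_name, "reason": str(exc),
                })
                logger.info("skipping %s/%s x %s: %s", act.trader_id,
                            act.day, mkt.index_name, exc)
    reject = np.zeros(len(results), dtype=bool)
    per_index_significant: dict[str, int] = {}
    per_index_ks: dict[str, dict] = {}
    index_names = sorted({r.index_name for r in results})
    for name in index_names:
        idx = [i for i, r in enumerate(results) if r.index_name == name]
        pvals = [results[i].p_value for i in idx]
        rej = holm_bonferroni(pvals, alpha=alpha)
        for i, flag in zip(idx, rej):
            reject[i] = bool(flag)
        per_index_significant[name] = int(rej.sum())
        D, ks_p = ks_uniformity(pvals)
        per_index_ks[name] = {"D": D, "p_value": ks_p, "n": len(pvals)}
    return GrangerScanResult(
        results=results,
        reject=reject.tolist(),
        per_index_significant=per_index_significant,
        per_index_ks=per_index_ks,
        alpha=alpha,
        skipped=skipped,
    )
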
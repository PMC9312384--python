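"""Attribution of average daily activation to trader-level factors.

The panel regression

    y_it = alpha + beta * division_i + gamma * gender_i + delta * amt_it
           + theta * experience_i + zeta * numT_it + eta' * vol_t

explains a trader-day's average activation with the trader's business
division (one-hot, first alphabetical level dropped), gender (binary
coded), the day's mean transaction dollar volume and transaction count,
trading experience in years, and the day's per-index market volatility
(standard deviation of minute-level first differences).  The fit is
ordinary least squares with classical standard errors; clustering by
trader is available since trader-days repeat within traders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .activation import ActivationSummary
from .errors import DegenerateDesignError, ValidationError
from .io_formats import MarketSeries, TraderProfile, TransactionLog

logger = logging.getLogger(__name__)


@dataclass
class AttributionResult:
    """OLS coefficient table for the activation attribution regression."""

    names: list[str]
    estimates: list[float]
    std_errors: list[float]
    t_values: list[float]
    p_values: list[float]
    n: int
    r_squared: float

    @classmethod
    def from_dict(cls, d: dict) -> "AttributionResult":
        return cls(**d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.estimates,
            "std_error": self.std_errors,
            "t_value": self.t_values,
            "p_value": self.p_values,
        }, index=self.names)


def daily_volatility(mkt: MarketSeries, day_minutes: np.ndarray | None = None
                     ) -> float:
    """Std (ddof 1) of the index's minute-level first differences."""
    vals = mkt.values
    if day_minutes is not None:
        sel = np.isin((mkt.timestamps // 60).astype(np.int64), day_minutes)
        vals = vals[sel]
    if vals.size < 3:
        return float("nan")
    return float(np.std(np.diff(vals), ddof=1))


def build_dataset(
    summaries: list[ActivationSummary],
    profiles: list[TraderProfile],
    transactions: TransactionLog,
    markets: dict[str, list[MarketSeries]] | None = None,
    day_spans: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Join summaries, survey covariates, trades, and market volatility.

    ``markets`` maps each day label to that day's market series;
    zero-trade days keep ``amt = 0`` and ``numT = 0`` rather than being
    dropped, preserving the panel shape.  Trader-days without a profile
    are excluded with a logged reason.
    """
    prof = {p.trader_id: p for p in profiles}
    rows = []
    for s in summaries:
        p = prof.get(s.trader_id)
        if p is None:
            logger.warning("dropping %s/%s: no trader profile", s.trader_id,
                           s.day)
            continue
        row = {
            "trader_id": s.trader_id,
            "day": s.day,
            "y": s.average_activation,
            "division": p.division,
            "gender": p.gender,
            "experience_years": p.experience_years,
        }
        if day_spans is not None and s.day in day_spans:
            lo, hi = day_spans[s.day]
            mask = (
                (transactions["trader_id"] == s.trader_id)
                & (transactions["timestamp"] >= lo)
                & (transactions["timestamp"] <= hi)
            )
        else:
            mask = transactions["trader_id"] == s.trader_id
        amounts = transactions.loc[mask, "amount_usd"]
        row["numT"] = int(mask.sum())
        row["amt"] = float(amounts.mean()) if row["numT"] else 0.0
        if markets is not None:
            for mkt in markets.get(s.day, []):
                row[f"vol_{mkt.index_name}"] = daily_volatility(mkt)
        rows.append(row)
    if not rows:
        raise ValidationError("attribution dataset is empty after joins")
    return pd.DataFrame(rows)


def design_matrix(ds: pd.DataFrame, log_amount: bool = False) -> pd.DataFrame:
    """Encode the regression design: intercept, dummies, and regressors."""
    X = pd.DataFrame(index=ds.index)
    X["const"] = 1.0
    divisions = sorted(ds["division"].unique())
    for level in divisions[1:]:  # first alphabetical level is the reference
        X[f"division[{level}]"] = (ds["division"] == level).astype(float)
    genders = sorted(ds["gender"].unique())
    if len(genders) > 2:
        raise ValidationError(f"gender must be binary, got {genders}")
    if len(genders) == 2:
        X[f"gender[{genders[1]}]"] = (ds["gender"] == genders[1]).astype(float)
    amt = ds["amt"].astype(float)
    X["amt"] = np.log1p(amt) if log_amount else amt
    X["experience_years"] = ds["experience_years"].astype(float)
    X["numT"] = ds["numT"].astype(float)
    for col in sorted(c for c in ds.columns if c.startswith("vol_")):
        X[col] = ds[col].astype(float)
    return X


def fit_attribution(
    ds: pd.DataFrame,
    log_amount: bool = False,
    cluster_by_trader: bool = False,
) -> AttributionResult:
    """Fit the attribution regression by ordinary least squares.

    Raises when the encoded design is rank deficient, naming the
    offending columns.
    """
    X = design_matrix(ds, log_amount=log_amount)
    y = ds["y"].astype(float)
    if len(ds) <= X.shape[1]:
        raise DegenerateDesignError(
            f"{len(ds)} rows cannot identify {X.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for col in X.columns:
            rest = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(col)
        raise DegenerateDesignError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {', '.join(bad) or 'unknown'}"
        )
    model = sm.OLS(y, X)
    if cluster_by_trader:
        fit = model.fit(cov_type="cluster",
                        cov_kwds={"groups": ds["trader_id"]})
    else:
        fit = model.fit()
    return AttributionResult(
        names=list(X.columns),
        estimates=[float(v) for v in fit.params],
        std_errors=[float(v) for v in fit.bse],
        t_values=[float(v) for v in fit.tvalues],
        p_values=[float(v) for v in fit.pvalues],
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )
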
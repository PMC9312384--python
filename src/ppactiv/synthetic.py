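"""Seeded synthetic trader cohorts with recoverable ground truth.

The generator emulates the *shape* of the study's proprietary data —
wristband physiology, minute-level market indices, transaction logs,
and survey covariates — not physiological realism.  Signal models are
deliberately simple:

* heart periods follow a mean-reverting AR(1) at beat scale (mean
  0.85 s, sd 0.05 s, phi = 0.95); beats accumulate into the IBI stream;
* electrodermal activity is a slow tonic drift plus phasic
  skin-conductance responses from a Poisson process (2/min at rest),
  each a 0.1–0.5 μS rise within 2 s decaying exponentially (tau 40 s);
* blood volume pulse is a unit oscillation at the instantaneous heart
  rate with slowly varying multiplicative amplitude noise;
* skin temperature is a slow random walk; acceleration is small noise.

*Activation episodes* perturb all four families simultaneously (heart
period mean -10% and variability -30%, SCR rate x4, BVP amplitude
x1.5, TEMP slope +0.003 °C/s), scaled by an episode magnitude and
ramped over 30 s, so the Mahalanobis pipeline has a recoverable truth.
Optional market coupling injects a trader-day's minute-level activation
driver into an index's increments ``lag`` minutes EARLIER, so the
market leads activation in the direction the Granger scan tests.
Transactions can plant post-transaction bumps (+15..+25 min, with a
smaller bump 5 minutes before) mirroring the event-study analysis.

Every random draw descends from the master seed through per-trader-day
``numpy.random.SeedSequence`` spawn keys, so cohorts are reproducible
under partial regeneration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import io_formats
from .errors import SpecificationError
from .io_formats import (
    ChannelSeries,
    IBISeries,
    MarketSeries,
    PhysioRecording,
    TraderProfile,
    TransactionLog,
)

#: Market indices monitored by the cohort (labels follow the study domain).
DEFAULT_INDICES = (
    "CDS_IG",
    "CDS_HY",
    "USD_Index",
    "UST_10Y_Future",
    "SP500_Emini_Future",
    "UST_5Y_Future",
    "Crude_Oil_Future",
    "VIX_Future",
)

DEFAULT_DIVISIONS = (
    "commodities", "credit", "equities", "fx", "g10-rates", "securitized",
)


@dataclass(frozen=True)
class PlantedEpisode:
    """A planted activation episode in epoch seconds."""

    start: float
    end: float
    magnitude: float = 1.0


@dataclass(frozen=True)
class Coupling:
    """Market -> activation coupling for one trader."""

    trader_id: str
    index_name: str
    lag_min: int
    strength: float


@dataclass(frozen=True)
class CohortSpec:
    """The stated world of the synthetic cohort.

    Scale defaults (55 traders, 5 days, 6.5 h sessions) follow the
    study design; device rates follow the wristband maker's public
    specification.  Effect sizes are chosen so that planted structure is
    recoverable by the corresponding pipeline stage without being
    trivially large.
    """

    n_traders: int = 55
    n_days: int = 5
    session_hours: float = 6.5
    base_epoch: int = 1_577_880_000  # 2020-01-01 12:00 UTC; arbitrary anchor
    divisions: tuple[str, ...] = DEFAULT_DIVISIONS
    # device sampling rates (Hz)
    bvp_rate: float = 64.0
    eda_rate: float = 4.0
    temp_rate: float = 4.0
    hr_rate: float = 1.0
    acc_rate: float = 32.0
    # baseline physiology
    heart_period_mean_s: float = 0.85
    heart_period_sd_s: float = 0.05
    heart_period_ar: float = 0.95
    scr_rate_per_min: float = 2.0
    scr_amp_range_us: tuple[float, float] = (0.1, 0.5)
    scr_rise_s: float = 2.0
    scr_decay_tau_s: float = 40.0
    eda_tonic_us: float = 0.3
    eda_drift_us_per_sqrt_s: float = 0.001
    eda_noise_us: float = 0.002
    temp_start_c: float = 33.0
    temp_walk_c_per_sqrt_s: float = 0.002
    bvp_amp_noise: float = 0.1
    acc_noise: float = 0.02
    # episode effects (at magnitude 1)
    ep_heart_mean_drop: float = 0.10
    ep_heart_sd_drop: float = 0.30
    ep_scr_rate_mult: float = 4.0
    ep_bvp_amp_mult: float = 1.5
    ep_temp_slope_c_per_s: float = 0.003
    ep_ramp_s: float = 30.0
    # planted spontaneous episodes
    episodes_per_day: int = 2
    episode_len_range_s: tuple[float, float] = (300.0, 900.0)
    episode_magnitude: float = 1.0
    # markets
    indices: tuple[str, ...] = DEFAULT_INDICES
    market_start: float = 100.0
    market_step_sd: float = 0.5
    coupled_fraction: float = 0.0
    coupling_index: str = "CDS_IG"
    coupling_lag_min: int = 3
    coupling_strength: float = 1.0
    driver_gain: float = 0.3
    # transactions
    transactions_per_day: float = 8.0
    amount_median_usd: float = 1e6
    amount_sigma: float = 1.0
    txn_bump_magnitude: float = 0.0  # 0 disables planted transaction bumps
    txn_post_bump_min: tuple[float, float] = (15.0, 25.0)
    txn_pre_bump_min: tuple[float, float] = (-5.0, 0.0)
    txn_pre_bump_ratio: float = 0.5
    # attribution planting: design-column name -> planted effect on the
    # episode-magnitude multiplier (per unit of the covariate)
    attribution_effects: dict = field(
        default_factory=lambda: {"experience_years": -0.02}
    )
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traders < 1 or self.n_days < 1:
            raise SpecificationError("n_traders and n_days must be >= 1")
        for r in (self.bvp_rate, self.eda_rate, self.temp_rate,
                  self.hr_rate, self.acc_rate):
            if r <= 0:
                raise SpecificationError("device rates must be > 0")

    @property
    def session_s(self) -> float:
        return self.session_hours * 3600.0

    def session_span(self, day_idx: int) -> tuple[float, float]:
        t0 = self.base_epoch + day_idx * 86400
        return (float(t0), float(t0 + self.session_s))

    def day_label(self, day_idx: int) -> str:
        return f"d{day_idx + 1}"


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for recovery tests."""

    seed: int
    episodes: dict  # "trader|day" -> list of [start, end, magnitude]
    couplings: list  # [trader_id, index_name, lag_min, strength]
    attribution_effects: dict
    txn_bump: dict
    dropped: list  # "trader|day" keys removed by dropout

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class Cohort:
    """In-memory synthetic cohort."""

    spec: CohortSpec
    recordings: list[PhysioRecording]
    markets: list[MarketSeries]
    transactions: TransactionLog
    profiles: list[TraderProfile]
    ground_truth: GroundTruth


def _rng(spec: CohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *key]))


# stream ids for per-trader-day substreams
_S_EPISODE, _S_PHYSIO, _S_TXN, _S_DRIVER, _S_MARKET, _S_PROFILE, _S_DROP = (
    range(7)
)


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def episode_envelope(
    episodes: list[PlantedEpisode],
    span: tuple[float, float],
    ramp_s: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-scaled trapezoidal envelope at 1 Hz over the span.

    Episodes ramp linearly over ``ramp_s`` at onset and offset; where
    episodes would overlap a SpecificationError is raised.
    """
    t0, t1 = span
    grid = np.arange(0.0, np.floor(t1 - t0) + 1.0)
    g = np.zeros_like(grid)
    eps = sorted(episodes, key=lambda e: e.start)
    for a, b in zip(eps, eps[1:]):
        if b.start < a.end:
            raise SpecificationError(
                f"overlapping planted episodes: ({a.start}, {a.end}) and "
                f"({b.start}, {b.end})"
            )
    for ep in eps:
        if ep.start < t0 or ep.end > t1:
            raise SpecificationError(
                f"episode ({ep.start}, {ep.end}) outside session {span}"
            )
        rel = grid + t0
        up = (rel - ep.start) / ramp_s
        down = (ep.end - rel) / ramp_s
        prof = np.clip(np.minimum(np.minimum(up, down), 1.0), 0.0, None)
        g = np.maximum(g, ep.magnitude * prof)
    return grid, g


def _envelope_at(times: np.ndarray, t0: float, grid: np.ndarray,
                 g: np.ndarray) -> np.ndarray:
    return np.interp(times - t0, grid, g)


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

def generate_physiology(
    spec: CohortSpec,
    trader_id: str,
    day: str,
    episodes: list[PlantedEpisode],
    rng: np.random.Generator,
    span: tuple[float, float] | None = None,
    driver_min: np.ndarray | None = None,
) -> PhysioRecording:
    """One trader-day of all channels with the given planted episodes.

    ``driver_min`` is an optional minute-level activation driver whose
    positive part additionally modulates heart period and SCR rate
    (used for market coupling).
    """
    if span is None:
        span = spec.session_span(0)
    t0, t1 = span
    dur = t1 - t0
    grid, g = episode_envelope(episodes, span, ramp_s=spec.ep_ramp_s)
    g_drive = g
    if driver_min is not None:
        drv = np.clip(driver_min, 0.0, None) * spec.driver_gain
        drv_1hz = np.repeat(drv, 60)[: grid.size]
        if drv_1hz.size < grid.size:
            drv_1hz = np.pad(drv_1hz, (0, grid.size - drv_1hz.size))
        g_drive = np.clip(g + drv_1hz, 0.0, None)

    # --- beats ---------------------------------------------------------
    phi = spec.heart_period_ar
    n_burn = 200
    n_max = int(dur / (spec.heart_period_mean_s * 0.6)) + n_burn + 16
    eps = rng.normal(0.0, np.sqrt(1.0 - phi**2), size=n_max)
    u = lfilter([1.0], [1.0, -phi], eps)[n_burn:]
    approx_t = np.cumsum(np.full(u.size, spec.heart_period_mean_s))
    g_beat = np.interp(approx_t, grid, g_drive)
    mean_k = spec.heart_period_mean_s * (
        1.0 - spec.ep_heart_mean_drop * g_beat
    )
    sd_k = spec.heart_period_sd_s * (
        1.0 - spec.ep_heart_sd_drop * np.minimum(g_beat, 1.0)
    )
    h = np.clip(mean_k + sd_k * u, 0.3, 2.0)
    beat_off = np.cumsum(h)
    keep = beat_off <= dur
    ibi = IBISeries(start_time=t0, offsets=beat_off[keep], rr=h[keep])

    # --- EDA -----------------------------------------------------------
    r_eda = spec.eda_rate
    n_eda = int(round(dur * r_eda))
    t_eda = np.arange(n_eda) / r_eda
    tonic = spec.eda_tonic_us + np.cumsum(
        rng.normal(0.0, spec.eda_drift_us_per_sqrt_s / np.sqrt(r_eda), n_eda)
    )
    tonic = np.clip(tonic, 0.05, None)
    rate_mult = 1.0 + (spec.ep_scr_rate_mult - 1.0) * np.interp(
        t_eda, grid, g_drive
    )
    max_rate = spec.scr_rate_per_min / 60.0 * float(rate_mult.max(initial=1.0))
    phasic = np.zeros(n_eda)
    n_cand = rng.poisson(max_rate * dur)
    cand = np.sort(rng.uniform(0.0, dur, size=n_cand))
    acc_p = (spec.scr_rate_per_min / 60.0) * np.interp(cand, t_eda, rate_mult)
    accepted = cand[rng.uniform(0.0, max_rate, size=n_cand) < acc_p]
    amp_lo, amp_hi = spec.scr_amp_range_us
    kern_len = int(round((spec.scr_rise_s + 6 * spec.scr_decay_tau_s) * r_eda))
    kt = np.arange(kern_len) / r_eda
    base_kernel = np.where(
        kt < spec.scr_rise_s,
        kt / spec.scr_rise_s,
        np.exp(-(kt - spec.scr_rise_s) / spec.scr_decay_tau_s),
    )
    for ev in accepted:
        amp = rng.uniform(amp_lo, amp_hi)
        i0 = int(np.floor(ev * r_eda))
        seg = min(kern_len, n_eda - i0)
        if seg > 0:
            phasic[i0 : i0 + seg] += amp * base_kernel[:seg]
    eda = tonic + phasic + rng.normal(0.0, spec.eda_noise_us, n_eda)
    eda_ch = ChannelSeries("EDA", t0, r_eda, np.clip(eda, 0.01, None))

    # --- TEMP ----------------------------------------------------------
    r_temp = spec.temp_rate
    n_temp = int(round(dur * r_temp))
    t_temp = np.arange(n_temp) / r_temp
    walk = np.cumsum(
        rng.normal(0.0, spec.temp_walk_c_per_sqrt_s / np.sqrt(r_temp), n_temp)
    )
    ep_drift = np.cumsum(
        spec.ep_temp_slope_c_per_s * np.interp(t_temp, grid, g) / r_temp
    )
    temp_ch = ChannelSeries(
        "TEMP", t0, r_temp, spec.temp_start_c + walk + ep_drift
    )

    # --- BVP -----------------------------------------------------------
    r_bvp = spec.bvp_rate
    n_bvp = int(round(dur * r_bvp))
    t_bvp = np.arange(n_bvp) / r_bvp
    h_inst = np.interp(t_bvp, beat_off[keep], h[keep]) if keep.any() else (
        np.full(n_bvp, spec.heart_period_mean_s)
    )
    phase = 2.0 * np.pi * np.cumsum(1.0 / h_inst) / r_bvp
    amp_ar = lfilter(
        [1.0], [1.0, -0.95],
        rng.normal(0.0, np.sqrt(1 - 0.95**2), int(np.ceil(dur)) + 1),
    )
    amp_noise = 1.0 + spec.bvp_amp_noise * np.interp(
        t_bvp, np.arange(amp_ar.size, dtype=float), amp_ar
    )
    amp_ep = 1.0 + (spec.ep_bvp_amp_mult - 1.0) * np.interp(t_bvp, grid, g)
    bvp_ch = ChannelSeries(
        "BVP", t0, r_bvp, amp_ep * amp_noise * np.sin(phase)
    )

    # --- ACC / HR (parsed and passed through only) ---------------------
    n_acc = int(round(dur * spec.acc_rate))
    acc = {
        f"ACC_{ax}": ChannelSeries(
            f"ACC_{ax}", t0, spec.acc_rate,
            base + rng.normal(0.0, spec.acc_noise, n_acc),
        )
        for ax, base in (("X", 0.0), ("Y", 0.0), ("Z", 1.0))
    }
    n_hr = int(round(dur * spec.hr_rate))
    t_hr = np.arange(n_hr) / spec.hr_rate
    hr_inst = 60.0 / np.interp(t_hr, beat_off[keep], h[keep])
    hr_ch = ChannelSeries(
        "HR", t0, spec.hr_rate, hr_inst + rng.normal(0.0, 1.0, n_hr)
    )

    channels = {"EDA": eda_ch, "TEMP": temp_ch, "BVP": bvp_ch, "HR": hr_ch}
    channels.update(acc)
    return PhysioRecording(
        trader_id=trader_id, day=day, channels=channels, ibi=ibi,
        session_span=span,
    )


# ---------------------------------------------------------------------------
# markets / transactions / helpers
# ---------------------------------------------------------------------------

def generate_markets(
    spec: CohortSpec,
    day_idx: int,
    rng: np.random.Generator,
    injections: dict[str, list[tuple[int, np.ndarray, float]]] | None = None,
) -> list[MarketSeries]:
    """Minute-level Gaussian random walks for one trading day.

    ``injections`` maps an index name to (lag_min, driver, strength)
    triples; the driver's value for minute ``tau`` is added to the
    index's increment at minute ``tau - lag``, so the market series
    leads the driver-modulated activation by ``lag`` minutes.
    """
    t0, t1 = spec.session_span(day_idx)
    n_min = int((t1 - t0) // 60) + 1
    minutes = (np.arange(n_min) * 60.0) + t0
    out = []
    for name in spec.indices:
        inc = rng.normal(0.0, spec.market_step_sd, n_min)
        for lag, driver, strength in (injections or {}).get(name, []):
            if lag < 1:
                raise SpecificationError("coupling lag must be >= 1 minute")
            m = min(driver.size, n_min)
            tau = np.arange(lag, m)
            inc[tau - lag] += strength * spec.market_step_sd * driver[tau]
        values = spec.market_start + np.cumsum(inc)
        out.append(MarketSeries(index_name=name, timestamps=minutes,
                                values=values))
    return out


def generate_transactions(
    spec: CohortSpec,
    trader_id: str,
    span: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[PlantedEpisode]]:
    """Poisson transaction times with log-normal amounts, plus bumps.

    When ``spec.txn_bump_magnitude > 0`` each transaction schedules a
    post-transaction episode over ``txn_post_bump_min`` and a smaller
    pre-transaction episode over ``txn_pre_bump_min``.
    """
    t0, t1 = span
    margin = 1860.0  # keep the ±30 min event-study neighbourhood inside
    lo, hi = t0 + margin, t1 - margin
    n = rng.poisson(spec.transactions_per_day) if hi > lo else 0
    times = np.sort(rng.uniform(lo, hi, size=n)) if n else np.zeros(0)
    amounts = spec.amount_median_usd * np.exp(
        rng.normal(0.0, spec.amount_sigma, size=n)
    )
    df = pd.DataFrame({
        "trader_id": trader_id,
        "timestamp": times,
        "amount_usd": amounts,
    })
    bumps: list[PlantedEpisode] = []
    if spec.txn_bump_magnitude > 0:
        for l in times:
            a, b = spec.txn_post_bump_min
            bumps.append(PlantedEpisode(l + a * 60, l + b * 60,
                                        spec.txn_bump_magnitude))
            a, b = spec.txn_pre_bump_min
            bumps.append(PlantedEpisode(
                l + a * 60, l + b * 60,
                spec.txn_bump_magnitude * spec.txn_pre_bump_ratio,
            ))
    return df, bumps


def _place_episodes(
    spec: CohortSpec,
    span: tuple[float, float],
    magnitude: float,
    rng: np.random.Generator,
) -> list[PlantedEpisode]:
    """Random non-overlapping spontaneous episodes after the burn-in."""
    t0, t1 = span
    episodes: list[PlantedEpisode] = []
    lo_len, hi_len = spec.episode_len_range_s
    for _ in range(spec.episodes_per_day):
        for _attempt in range(50):
            length = rng.uniform(lo_len, hi_len)
            if t1 - length - 60.0 <= t0 + 900.0:
                continue  # session too short for this episode
            start = rng.uniform(t0 + 900.0, t1 - length - 60.0)
            cand = PlantedEpisode(start, start + length, magnitude)
            if all(cand.end <= e.start or cand.start >= e.end
                   for e in episodes):
                episodes.append(cand)
                break
    return sorted(episodes, key=lambda e: e.start)


def _merge_nonoverlapping(
    base: list[PlantedEpisode], extra: list[PlantedEpisode]
) -> list[PlantedEpisode]:
    """Add ``extra`` episodes, dropping any that overlap what is kept."""
    out = sorted(base, key=lambda e: e.start)
    for ep in sorted(extra, key=lambda e: e.start):
        if all(ep.end <= e.start or ep.start >= e.end for e in out):
            out.append(ep)
            out.sort(key=lambda e: e.start)
    return out


def _magnitude_multiplier(
    spec: CohortSpec, profile: TraderProfile
) -> float:
    """Episode-magnitude multiplier implementing the planted covariate
    effects (e.g. a negative experience effect on activation load)."""
    eta = 0.0
    for name, coef in spec.attribution_effects.items():
        if name == "experience_years":
            eta += coef * profile.experience_years
        elif name.startswith("gender[") and name[7:-1] == profile.gender:
            eta += coef
        elif name.startswith("division[") and name[9:-1] == profile.division:
            eta += coef
    return float(np.clip(1.0 + eta, 0.2, 3.0))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: recordings, markets, trades, profiles.

    Dropout removes ``round(dropout_rate * n_traders * n_days)``
    trader-days chosen deterministically from the master seed (a
    12% rate on the default 275 trader-days leaves the study's 242).
    """
    rng_prof = _rng(spec, _S_PROFILE)
    profiles = []
    for i in range(spec.n_traders):
        profiles.append(TraderProfile(
            trader_id=f"T{i + 1:03d}",
            gender=str(rng_prof.choice(["female", "male"])),
            experience_years=float(np.round(rng_prof.uniform(1.0, 25.0), 1)),
            division=str(rng_prof.choice(list(spec.divisions))),
        ))
    n_coupled = int(round(spec.coupled_fraction * spec.n_traders))
    couplings = [
        Coupling(profiles[i].trader_id, spec.coupling_index,
                 spec.coupling_lag_min, spec.coupling_strength)
        for i in range(n_coupled)
    ]
    coupled_ids = {c.trader_id for c in couplings}

    keys = [(i, d) for i in range(spec.n_traders) for d in range(spec.n_days)]
    n_drop = int(round(spec.dropout_rate * len(keys)))
    rng_drop = _rng(spec, _S_DROP)
    drop_idx = set(
        rng_drop.choice(len(keys), size=n_drop, replace=False).tolist()
    ) if n_drop else set()

    recordings: list[PhysioRecording] = []
    txn_frames: list[pd.DataFrame] = []
    gt_episodes: dict[str, list] = {}
    dropped: list[str] = []
    drivers: dict[int, list[tuple[int, np.ndarray, float]]] = {}

    for ki, (i, d) in enumerate(keys):
        profile = profiles[i]
        day = spec.day_label(d)
        key = f"{profile.trader_id}|{day}"
        if ki in drop_idx:
            dropped.append(key)
            continue
        span = spec.session_span(d)
        mag = spec.episode_magnitude * _magnitude_multiplier(spec, profile)
        episodes = _place_episodes(spec, span, mag, _rng(spec, i, d, _S_EPISODE))
        txns, bumps = generate_transactions(
            spec, profile.trader_id, span, _rng(spec, i, d, _S_TXN)
        )
        txn_frames.append(txns)
        episodes = _merge_nonoverlapping(episodes, bumps)
        driver_min = None
        if profile.trader_id in coupled_ids:
            n_min = int((span[1] - span[0]) // 60) + 1
            driver_min = _rng(spec, i, d, _S_DRIVER).normal(0.0, 1.0, n_min)
            drivers.setdefault(d, []).append(
                (spec.coupling_lag_min, driver_min, spec.coupling_strength)
            )
        rec = generate_physiology(
            spec, profile.trader_id, day, episodes,
            _rng(spec, i, d, _S_PHYSIO), span=span, driver_min=driver_min,
        )
        recordings.append(rec)
        gt_episodes[key] = [[e.start, e.end, e.magnitude] for e in episodes]

    markets: list[MarketSeries] = []
    per_index: dict[str, list[MarketSeries]] = {}
    for d in range(spec.n_days):
        inj = {spec.coupling_index: drivers.get(d, [])} if drivers.get(d) \
            else None
        for mkt in generate_markets(spec, d, _rng(spec, d, _S_MARKET), inj):
            per_index.setdefault(mkt.index_name, []).append(mkt)
    for name in spec.indices:
        parts = per_index.get(name, [])
        markets.append(MarketSeries(
            index_name=name,
            timestamps=np.concatenate([m.timestamps for m in parts]),
            values=np.concatenate([m.values for m in parts]),
        ))

    transactions = (
        pd.concat(txn_frames, ignore_index=True) if txn_frames
        else pd.DataFrame(columns=list(io_formats.TRANSACTION_COLUMNS))
    )
    ground_truth = GroundTruth(
        seed=spec.seed,
        episodes=gt_episodes,
        couplings=[[c.trader_id, c.index_name, c.lag_min, c.strength]
                   for c in couplings],
        attribution_effects=dict(spec.attribution_effects),
        txn_bump={
            "magnitude": spec.txn_bump_magnitude,
            "post_window_min": list(spec.txn_post_bump_min),
            "pre_window_min": list(spec.txn_pre_bump_min),
            "pre_ratio": spec.txn_pre_bump_ratio,
        },
        dropped=dropped,
    )
    return Cohort(
        spec=spec, recordings=recordings, markets=markets,
        transactions=transactions, profiles=profiles,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# cohort persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort in the on-disk layout the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        d = out / rec.trader_id / rec.day
        d.mkdir(parents=True, exist_ok=True)
        for name, ch in rec.channels.items():
            io_formats.write_channel_csv(ch, d / f"{name}.csv")
        io_formats.write_ibi_csv(rec.ibi, d / "IBI.csv")
        with open(d / "session.txt", "w") as fh:
            fh.write(f"{float(rec.session_span[0])!r},"
                     f"{float(rec.session_span[1])!r}\n")
    io_formats.write_markets_csv(cohort.markets, out / "markets.csv")
    io_formats.write_transactions_csv(cohort.transactions,
                                      out / "transactions.csv")
    io_formats.write_profiles_csv(cohort.profiles, out / "profiles.csv")
    io_formats.write_results(cohort.ground_truth, out / "ground_truth.json")


def read_cohort(data_dir: str | Path) -> Cohort | None:
    """Read a cohort directory written by :func:`write_cohort`.

    The returned Cohort carries a default spec (the true spec is not
    serialised; the ground-truth file records what was planted).
    """
    data = Path(data_dir)
    recordings = []
    for trader_dir in sorted(p for p in data.iterdir() if p.is_dir()):
        for day_dir in sorted(p for p in trader_dir.iterdir() if p.is_dir()):
            channels = {}
            for f in sorted(day_dir.glob("*.csv")):
                if f.stem == "IBI":
                    continue
                channels[f.stem] = io_formats.read_channel_csv(f)
            ibi = io_formats.read_ibi_csv(day_dir / "IBI.csv")
            span_txt = (day_dir / "session.txt").read_text().strip()
            a, b = (float(v) for v in span_txt.split(","))
            recordings.append(PhysioRecording(
                trader_id=trader_dir.name, day=day_dir.name,
                channels=channels, ibi=ibi, session_span=(a, b),
            ))
    markets = io_formats.read_markets_csv(data / "markets.csv")
    transactions = io_formats.read_transactions_csv(data / "transactions.csv")
    profiles = io_formats.read_profiles_csv(data / "profiles.csv")
    ground_truth = io_formats.read_results(data / "ground_truth.json")
    return Cohort(
        spec=CohortSpec(), recordings=recordings, markets=markets,
        transactions=transactions, profiles=profiles,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# direct synthesis helpers for stage-level truth recovery
# ---------------------------------------------------------------------------

def coupled_minute_pair(
    n_minutes: int,
    lag_min: int,
    strength: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Minute-difference pair where the market change leads activation.

    Returns ``(dy, dm)`` with ``dy_t = strength * dm_{t-lag} + noise``;
    ``strength = 0`` gives independent white noise (the global null).
    """
    dm = rng.normal(0.0, 1.0, n_minutes)
    dy = rng.normal(0.0, noise_sd, n_minutes)
    if strength != 0.0 and lag_min >= 1:
        dy[lag_min:] += strength * dm[:-lag_min]
    return dy, dm


def synthesize_attribution_dataset(
    truth: dict[str, float],
    n_rows: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    divisions: tuple[str, ...] = DEFAULT_DIVISIONS,
    n_indices: int = 2,
) -> pd.DataFrame:
    """Panel rows drawn from a known linear model for recovery tests.

    ``truth`` maps design-column names (as produced by
    :func:`ppactiv.attribution.design_matrix`) to coefficients; missing
    columns get coefficient 0.  The ``amt`` column is in millions of
    USD so that all regressors share a comparable scale.
    """
    div = rng.choice(list(divisions), size=n_rows)
    gender = rng.choice(["female", "male"], size=n_rows)
    ds = pd.DataFrame({
        "trader_id": [f"T{i % 50:03d}" for i in range(n_rows)],
        "day": [f"d{i % 5 + 1}" for i in range(n_rows)],
        "division": div,
        "gender": gender,
        "amt": rng.lognormal(0.0, 1.0, n_rows),  # millions USD
        "experience_years": rng.uniform(1.0, 25.0, n_rows),
        "numT": rng.poisson(8.0, n_rows).astype(float),
    })
    for j in range(n_indices):
        ds[f"vol_idx{j}"] = rng.uniform(0.05, 0.5, n_rows)
    from .attribution import design_matrix

    X = design_matrix(ds)
    beta = np.array([truth.get(c, 0.0) for c in X.columns])
    y = X.to_numpy() @ beta
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_rows)
    ds["y"] = y
    return ds


def generate_event_study_cohort(
    n_trader_days: int,
    rng: np.random.Generator,
    txns_per_day: int = 3,
    session_s: float = 4 * 3600.0,
    base_mean: float = 4.0,
    base_sd: float = 1.0,
    post_bump_z: float = 0.3,
    pre_bump_z: float = 0.15,
) -> tuple[list, TransactionLog]:
    """Activation series with planted z-bumps around transactions.

    Baseline activation is i.i.d. normal; each transaction adds
    ``post_bump_z`` day-standard-deviations over [+15, +25) minutes and
    ``pre_bump_z`` over [-5, 0).  Returns series plus the transaction
    log, for exercising the event-study stage against a known profile.
    """
    from .activation import ActivationSeries

    acts = []
    rows = []
    t0 = 1_600_000_000
    n = int(session_s)
    for k in range(n_trader_days):
        start = t0 + k * 86400
        ts = np.arange(start, start + n, dtype=np.int64)
        dm = rng.normal(base_mean, base_sd, n)
        txn_times = np.sort(rng.uniform(start + 35 * 60,
                                        start + n - 35 * 60, txns_per_day))
        for l in txn_times:
            post = (ts >= l + 15 * 60) & (ts < l + 25 * 60)
            pre = (ts >= l - 5 * 60) & (ts < l)
            dm[post] += post_bump_z * base_sd
            dm[pre] += pre_bump_z * base_sd
            rows.append({"trader_id": f"T{k:03d}", "timestamp": float(l),
                         "amount_usd": 1e6})
        mu = float(dm.mean())
        sd = float(dm.std(ddof=1))
        acts.append(ActivationSeries(
            trader_id=f"T{k:03d}", day="d1", timestamps=ts, dm=dm,
            valid=np.ones(n, dtype=bool), day_mean=mu, day_std=sd,
            z=(dm - mu) / sd,
        ))
    return acts, pd.DataFrame(rows)
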
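"""Readers and writers for wearable-device exports, market data, and results.

Channel files follow the wristband maker's public export dialect: line 1 is
the recording start time in epoch seconds UTC, line 2 the sampling rate in
Hz, and every following line one sample.  Inter-beat-interval (IBI) files
carry the start time on line 1 and ``offset_s,rr_s`` pairs afterwards; the
offset is the beat time relative to the start, the second value the length
of the preceding inter-beat interval.  Market series, transaction logs, and
trader profiles are ordinary headered CSV tables.  Analysis results are
written as JSON documents tagged with the producing object's kind, the
package version, and an optional configuration hash so that a result file
can be read back into the object it came from.

All timestamps are epoch seconds UTC; session-local clock handling is the
caller's responsibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Columns required of a transaction log table.
TRANSACTION_COLUMNS = ("trader_id", "timestamp", "amount_usd")
#: Columns required of a market table.
MARKET_COLUMNS = ("index_name", "timestamp", "value")
#: Columns required of a trader profile table.
PROFILE_COLUMNS = ("trader_id", "gender", "experience_years", "division")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ChannelSeries:
    """A uniformly sampled physiological channel.

    Sample ``k`` is taken at ``start_time + k / rate_hz``.  Units depend on
    the channel: microsiemens for EDA, degrees Celsius for TEMP, beats per
    minute for HR, and device units for BVP and the accelerometer axes.
    Missing samples are encoded as NaN.
    """

    name: str
    start_time: float
    rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.rate_hz > 0:
            raise ValidationError(f"rate_hz must be > 0, got {self.rate_hz}")
        if self.values.ndim != 1:
            raise ValidationError("channel values must be one-dimensional")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Epoch-second timestamp of every sample."""
        return self.start_time + np.arange(self.n) / self.rate_hz

    @property
    def end_time(self) -> float:
        return self.start_time + max(self.n - 1, 0) / self.rate_hz


@dataclass
class IBISeries:
    """Irregular stream of heartbeats with their preceding RR intervals."""

    start_time: float
    offsets: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.offsets.shape != self.rr.shape or self.offsets.ndim != 1:
            raise ValidationError("offsets and rr must be matching 1-d arrays")
        if self.offsets.size and np.any(np.diff(self.offsets) <= 0):
            raise ValidationError("non-increasing offsets in IBI series")
        if np.any(self.rr <= 0):
            raise ValidationError("rr intervals must be > 0")

    @property
    def n(self) -> int:
        return int(self.offsets.size)

    @property
    def times(self) -> np.ndarray:
        """Epoch-second time of each beat."""
        return self.start_time + self.offsets


@dataclass
class PhysioRecording:
    """One trader-day's channels plus the beat stream."""

    trader_id: str
    day: str
    channels: dict[str, ChannelSeries]
    ibi: IBISeries
    session_span: tuple[float, float]


@dataclass
class MarketSeries:
    """Minute-level levels of one market index."""

    index_name: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValidationError("timestamps and values must match in length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("market timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.timestamps.size)


#: A transaction log is a DataFrame with TRANSACTION_COLUMNS.
TransactionLog = pd.DataFrame


@dataclass(frozen=True)
class TraderProfile:
    """Survey covariates of one trader."""

    trader_id: str
    gender: str
    experience_years: float
    division: str

    def __post_init__(self) -> None:
        if self.experience_years < 0:
            raise ValidationError(
                f"experience_years must be >= 0, got {self.experience_years}"
            )


# ---------------------------------------------------------------------------
# channel / IBI files
# ---------------------------------------------------------------------------

def _parse_header_number(line: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(line.strip())
    except ValueError as exc:
        raise FormatError(
            f"{path}: line {lineno}: expected {what}, got {line.strip()!r}"
        ) from exc


def read_channel_csv(path: str | Path) -> ChannelSeries:
    """Read a device-export channel file.

    The channel name is inferred from the file-name stem.  Empty lines and
    literal ``nan`` entries become missing samples (NaN).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, expected a start-time header")
    start = _parse_header_number(lines[0], path, 1, "epoch start time")
    if len(lines) < 2:
        raise FormatError(f"{path}: line 2: missing sampling-rate header")
    rate = _parse_header_number(lines[1], path, 2, "sampling rate in Hz")
    if rate <= 0:
        raise FormatError(f"{path}: line 2: sampling rate must be > 0, got {rate}")
    vals = np.empty(len(lines) - 2, dtype=float)
    for i, raw in enumerate(lines[2:], start=3):
        s = raw.strip()
        if s == "" or s.lower() == "nan":
            vals[i - 3] = np.nan
            continue
        try:
            vals[i - 3] = float(s)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-numeric sample {s!r}") from exc
    return ChannelSeries(name=path.stem, start_time=start, rate_hz=rate, values=vals)


def write_channel_csv(channel: ChannelSeries, path: str | Path) -> None:
    """Write a channel in the device-export dialect at full double precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{float(channel.start_time)!r}\n{float(channel.rate_hz)!r}\n")
        fh.write("\n".join("nan" if np.isnan(v) else repr(float(v))
                           for v in channel.values))
        if channel.n:
            fh.write("\n")


def read_ibi_csv(path: str | Path) -> IBISeries:
    """Read an inter-beat-interval file (start header, then offset,rr pairs)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, expected a start-time header")
    start = _parse_header_number(lines[0], path, 1, "epoch start time")
    offsets, rr = [], []
    for i, raw in enumerate(lines[1:], start=2):
        s = raw.strip()
        if not s:
            continue
        parts = s.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {i}: expected 'offset_s,rr_s', got {s!r}")
        try:
            offsets.append(float(parts[0]))
            rr.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-numeric entry in {s!r}") from exc
    try:
        return IBISeries(start_time=start, offsets=np.array(offsets), rr=np.array(rr))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_ibi_csv(ibi: IBISeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{float(ibi.start_time)!r}\n")
        for off, r in zip(ibi.offsets, ibi.rr):
            fh.write(f"{float(off)!r},{float(r)!r}\n")


# ---------------------------------------------------------------------------
# tabular files
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s): %s", path, ", ".join(extra))
    return df[list(required)]


def read_markets_csv(path: str | Path) -> list[MarketSeries]:
    """Read every index present in a markets table, one MarketSeries each."""
    df = _read_table(path, MARKET_COLUMNS)
    out = []
    for name, grp in df.groupby("index_name", sort=True):
        grp = grp.sort_values("timestamp")
        out.append(MarketSeries(index_name=str(name),
                                timestamps=grp["timestamp"].to_numpy(float),
                                values=grp["value"].to_numpy(float)))
    return out


def read_market_csv(path: str | Path, index_name: str | None = None) -> MarketSeries:
    """Read a single index from a markets table.

    ``index_name`` may be omitted when the file contains exactly one index.
    """
    series = read_markets_csv(path)
    if index_name is None:
        if len(series) != 1:
            raise ValidationError(
                f"{path}: contains {len(series)} indices; pass index_name"
            )
        return series[0]
    for s in series:
        if s.index_name == index_name:
            return s
    raise ValidationError(f"{path}: index {index_name!r} not present")


def write_markets_csv(series: Iterable[MarketSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"index_name": s.index_name,
                      "timestamp": s.timestamps,
                      "value": s.values})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_transactions_csv(path: str | Path) -> TransactionLog:
    df = _read_table(path, TRANSACTION_COLUMNS)
    if (df["amount_usd"] <= 0).any():
        bad = df.loc[df["amount_usd"] <= 0].index[0]
        raise ValidationError(
            f"{path}: row {bad}: amount_usd must be > 0, got "
            f"{df.loc[bad, 'amount_usd']}"
        )
    df["trader_id"] = df["trader_id"].astype(str)
    return df.reset_index(drop=True)


def write_transactions_csv(log: TransactionLog, path: str | Path) -> None:
    log[list(TRANSACTION_COLUMNS)].to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[TraderProfile]:
    df = _read_table(path, PROFILE_COLUMNS)
    return [
        TraderProfile(trader_id=str(r.trader_id), gender=str(r.gender),
                      experience_years=float(r.experience_years),
                      division=str(r.division))
        for r in df.itertuples(index=False)
    ]


def write_profiles_csv(profiles: Iterable[TraderProfile], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in profiles])[
        list(PROFILE_COLUMNS)
    ].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result documents
# ---------------------------------------------------------------------------

def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _result_registry() -> dict[str, Any]:
    # imported lazily to avoid circular imports with the analysis modules
    from . import activation, attribution, causality, event_study, synthetic

    return {
        "ActivationSummary": activation.ActivationSummary,
        "HistogramSet": activation.HistogramSet,
        "GrangerResult": causality.GrangerResult,
        "GrangerScanResult": causality.GrangerScanResult,
        "AttributionResult": attribution.AttributionResult,
        "EventStudyProfile": event_study.EventStudyProfile,
        "GroundTruth": synthetic.GroundTruth,
    }


def write_results(obj: Any, path: str | Path, config_hash: str | None = None) -> None:
    """Write an analysis result as a kind-tagged JSON document."""
    from . import __version__

    kind = type(obj).__name__
    if kind not in _result_registry():
        raise ValidationError(f"unknown result type {kind!r}")
    doc = {
        "kind": kind,
        "version": __version__,
        "config_hash": config_hash,
        "payload": _jsonify(obj),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_results(path: str | Path) -> Any:
    """Read a result document back into the object it was written from."""
    with open(path) as fh:
        doc = json.load(fh)
    registry = _result_registry()
    kind = doc.get("kind")
    if kind not in registry:
        raise FormatError(f"{path}: unknown result kind {kind!r}")
    return registry[kind].from_dict(doc["payload"])
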
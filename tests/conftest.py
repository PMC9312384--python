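import numpy as np
import pytest

from ppactiv.activation import ActivationSeries
from ppactiv.features import FEATURE_NAMES, FeatureSeries
from ppactiv.io_formats import ChannelSeries, IBISeries


def make_channel(values, rate_hz=4.0, start=0.0, name="EDA"):
    return ChannelSeries(name=name, start_time=start, rate_hz=rate_hz,
                         values=np.asarray(values, float))


def make_ibi(rr, start=0.0):
    """IBI stream of consecutive beats with the given RR intervals (s)."""
    rr = np.asarray(rr, float)
    return IBISeries(start_time=start, offsets=np.cumsum(rr), rr=rr)


def make_features(matrix, start=0, valid=None):
    """FeatureSeries on a 1 Hz grid starting at ``start`` seconds."""
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return FeatureSeries(
        trader_id="T", day="d1",
        timestamps=np.arange(start, start + n, dtype=np.int64),
        matrix=matrix, valid=np.asarray(valid, bool),
    )


def make_activation(dm, start=0, valid=None, trader_id="T", day="d1"):
    """ActivationSeries with day stats computed from the given values."""
    dm = np.asarray(dm, float)
    n = dm.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, bool)
    vals = dm[valid]
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    z = np.full(n, np.nan)
    z[valid] = (vals - mu) / sd if sd > 0 else 0.0
    return ActivationSeries(
        trader_id=trader_id, day=day,
        timestamps=np.arange(start, start + n, dtype=np.int64),
        dm=dm, valid=valid, day_mean=mu, day_std=sd, z=z,
    )


@pytest.fixture(scope="session")
def one_hour_recording():
    """A seeded baseline (no planted episodes) one-hour recording."""
    from ppactiv import synthetic

    spec = synthetic.CohortSpec(session_hours=1.0, seed=11)
    return synthetic.generate_physiology(
        spec, "T001", "d1", [], np.random.default_rng(11),
        span=spec.session_span(0),
    )
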
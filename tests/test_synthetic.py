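"""Determinism and planted-structure bookkeeping of the cohort generator."""

import numpy as np
import pytest

from ppactiv import io_formats, synthetic
from ppactiv.errors import SpecificationError
from ppactiv.synthetic import (
    CohortSpec,
    PlantedEpisode,
    episode_envelope,
    generate_cohort,
    generate_markets,
    generate_physiology,
    generate_transactions,
)


class TestEnvelope:
    def test_trapezoid_shape(self):
        grid, g = episode_envelope(
            [PlantedEpisode(100.0, 400.0, 2.0)], (0.0, 600.0), ramp_s=30.0
        )
        assert g[50] == 0.0
        assert g[115] == pytest.approx(1.0)  # half-way up the ramp
        assert g[200] == pytest.approx(2.0)  # plateau at magnitude
        assert g[400] == pytest.approx(0.0)
        assert g[500] == 0.0

    def test_overlap_rejected(self):
        with pytest.raises(SpecificationError, match="overlap"):
            episode_envelope(
                [PlantedEpisode(0.0, 100.0), PlantedEpisode(50.0, 150.0)],
                (0.0, 600.0),
            )

    def test_outside_span_rejected(self):
        with pytest.raises(SpecificationError, match="outside"):
            episode_envelope([PlantedEpisode(500.0, 700.0)], (0.0, 600.0))


class TestPhysiology:
    def test_same_seed_identical(self):
        spec = CohortSpec(session_hours=0.5, seed=1)
        span = spec.session_span(0)
        eps = [PlantedEpisode(span[0] + 600, span[0] + 900, 1.0)]
        a = generate_physiology(spec, "T", "d1", eps,
                                np.random.default_rng(42), span=span)
        b = generate_physiology(spec, "T", "d1", eps,
                                np.random.default_rng(42), span=span)
        np.testing.assert_array_equal(a.ibi.rr, b.ibi.rr)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].values,
                                          b.channels[name].values)

    def test_channel_inventory_and_rates(self, one_hour_recording):
        rec = one_hour_recording
        assert set(rec.channels) == {
            "EDA", "TEMP", "BVP", "HR", "ACC_X", "ACC_Y", "ACC_Z"
        }
        assert rec.channels["BVP"].rate_hz == 64.0
        assert rec.channels["EDA"].n == 4 * 3600
        # heart periods hover around the configured mean
        assert rec.ibi.rr.mean() == pytest.approx(0.85, abs=0.05)

    def test_episode_raises_heart_rate(self):
        spec = CohortSpec(session_hours=1.0, seed=2)
        span = spec.session_span(0)
        eps = [PlantedEpisode(span[0] + 1200, span[0] + 2400, 1.0)]
        rec = generate_physiology(spec, "T", "d1", eps,
                                  np.random.default_rng(7), span=span)
        t = rec.ibi.times
        inside = (t > span[0] + 1300) & (t < span[0] + 2300)
        outside = (t < span[0] + 1100) | (t > span[0] + 2500)
        assert rec.ibi.rr[inside].mean() < 0.95 * rec.ibi.rr[outside].mean()


class TestMarkets:
    def test_null_increments_are_white(self):
        spec = CohortSpec(session_hours=6.5, seed=3)
        mkts = generate_markets(spec, 0, np.random.default_rng(3))
        assert len(mkts) == len(spec.indices)
        inc = np.diff(mkts[0].values)
        acf1 = np.corrcoef(inc[:-1], inc[1:])[0, 1]
        assert abs(acf1) < 0.12
        assert np.all(np.diff(mkts[0].timestamps) == 60.0)

    def test_injection_leads_driver(self):
        spec = CohortSpec(session_hours=6.5, seed=4)
        n_min = int(spec.session_s // 60) + 1
        driver = np.random.default_rng(5).normal(size=n_min)
        lag = 3
        mkts = generate_markets(
            spec, 0, np.random.default_rng(6),
            injections={spec.indices[0]: [(lag, driver, 1.0)]},
        )
        inc = np.diff(mkts[0].values)
        # increment at tau-lag carries driver[tau]
        r = np.corrcoef(inc[: n_min - lag - 1], driver[lag + 1 :])[0, 1]
        assert r > 0.5

    def test_bad_lag_rejected(self):
        spec = CohortSpec(seed=0)
        with pytest.raises(SpecificationError, match="lag"):
            generate_markets(
                spec, 0, np.random.default_rng(0),
                injections={spec.indices[0]: [(0, np.zeros(10), 1.0)]},
            )


class TestTransactions:
    def test_zero_rate_empty(self):
        spec = CohortSpec(transactions_per_day=0.0, seed=0)
        df, bumps = generate_transactions(spec, "T", spec.session_span(0),
                                          np.random.default_rng(0))
        assert len(df) == 0 and bumps == []

    def test_poisson_mean(self):
        spec = CohortSpec(transactions_per_day=8.0, seed=0)
        counts = [
            len(generate_transactions(spec, "T", spec.session_span(0),
                                      np.random.default_rng(s))[0])
            for s in range(100)
        ]
        se = np.sqrt(8.0 / 100)
        assert abs(np.mean(counts) - 8.0) < 3 * se

    def test_bumps_once_per_transaction(self):
        spec = CohortSpec(transactions_per_day=5.0, txn_bump_magnitude=0.8,
                          seed=0)
        df, bumps = generate_transactions(spec, "T", spec.session_span(0),
                                          np.random.default_rng(1))
        assert len(bumps) == 2 * len(df)  # one post + one pre bump each
        for l, post, pre in zip(df["timestamp"], bumps[::2], bumps[1::2]):
            assert post.start == pytest.approx(l + 15 * 60)
            assert post.end == pytest.approx(l + 25 * 60)
            assert pre.end == pytest.approx(l)
            assert pre.magnitude == pytest.approx(0.8 * 0.5)


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(n_traders=2, n_days=2, session_hours=0.5,
                      transactions_per_day=2.0, seed=9)
    return generate_cohort(spec)


class TestCohort:
    def test_counts_and_keys(self, small_cohort):
        c = small_cohort
        assert len(c.recordings) == 4
        assert len(c.profiles) == 2
        assert len(c.markets) == len(c.spec.indices)
        keys = {f"{r.trader_id}|{r.day}" for r in c.recordings}
        assert set(c.ground_truth.episodes) == keys

    def test_dropout_exact_quota(self):
        spec = CohortSpec(n_traders=5, n_days=5, session_hours=0.25,
                          episodes_per_day=0, transactions_per_day=0.0,
                          dropout_rate=0.12, seed=1)
        c = generate_cohort(spec)
        assert len(c.recordings) == 25 - round(0.12 * 25)
        assert len(c.ground_truth.dropped) == round(0.12 * 25)

    def test_ground_truth_round_trip(self, small_cohort, tmp_path):
        io_formats.write_results(small_cohort.ground_truth,
                                 tmp_path / "gt.json")
        back = io_formats.read_results(tmp_path / "gt.json")
        assert back == small_cohort.ground_truth

    def test_cohort_write_read_round_trip(self, small_cohort, tmp_path):
        synthetic.write_cohort(small_cohort, tmp_path / "cohort")
        back = synthetic.read_cohort(tmp_path / "cohort")
        assert len(back.recordings) == len(small_cohort.recordings)
        a = small_cohort.recordings[0]
        b = next(r for r in back.recordings
                 if (r.trader_id, r.day) == (a.trader_id, a.day))
        np.testing.assert_allclose(b.ibi.rr, a.ibi.rr, rtol=1e-12)
        np.testing.assert_allclose(b.channels["EDA"].values,
                                   a.channels["EDA"].values, rtol=1e-12)
        assert b.session_span == a.session_span
        assert back.ground_truth == small_cohort.ground_truth

    def test_experience_lowers_episode_magnitude(self):
        spec = CohortSpec(seed=0)
        young = io_formats.TraderProfile("a", "female", 1.0, "fx")
        old = io_formats.TraderProfile("b", "female", 25.0, "fx")
        from ppactiv.synthetic import _magnitude_multiplier

        assert _magnitude_multiplier(spec, old) < \
            _magnitude_multiplier(spec, young)
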
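"""Daily volume, potential exposure, first-retweet latency, rank tests."""

from __future__ import annotations

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, strategies as st

from credflow.temporal import (
    Ecdf,
    daily_volume,
    first_retweet_latency,
    potential_exposure,
    rank_test,
    retweeted_fraction,
)

from conftest import make_record


class TestDailyVolume:
    def test_counts_land_on_their_dates(self, windows):
        recs = [
            make_record(tweet_id=f"t{i}", when="2021-03-05T08:00:00") for i in range(3)
        ]
        s = daily_volume(recs, windows)
        assert s[date(2021, 3, 5)] == 3
        assert s.drop(date(2021, 3, 5)).eq(0).all()
        assert len(s) == 22

    def test_scale_is_metadata_only(self, windows):
        recs = [make_record()]
        s = daily_volume(recs, windows, scale=20)
        assert s.attrs["scale"] == 20
        assert s.sum() == 1  # stored values never scaled

    def test_empty_records_give_all_zero_series(self, windows):
        s = daily_volume([], windows)
        assert s.eq(0).all() and len(s) == 22

    def test_sum_equals_record_count_in_window(self, windows, default_stream):
        _, _, records, _ = default_stream
        sample = records[:5000]
        assert daily_volume(sample, windows).sum() == len(sample)


class TestPotentialExposure:
    def test_daily_sums_and_mean(self, windows):
        recs = [
            make_record(tweet_id="a", when="2021-03-05T08:00:00", followers=1200),
            make_record(tweet_id="b", when="2021-03-06T08:00:00", followers=300),
        ]
        exp = potential_exposure(recs, windows)
        assert exp.series[date(2021, 3, 5)] == 1200
        assert exp.series[date(2021, 3, 6)] == 300
        assert exp.mean == 750

    def test_all_zero_followers(self, windows):
        recs = [make_record(tweet_id=f"t{i}", followers=0) for i in range(4)]
        exp = potential_exposure(recs, windows)
        assert exp.series.eq(0).all() and exp.mean == 0 and exp.sd == 0

    def test_mean_and_sd_against_spreadsheet_oracle(self, windows):
        # Frozen from an independent spreadsheet-style computation:
        # mean([10,10,10,10,1000]) = 208, sample SD = 442.7415 (STDEV).
        recs = [
            make_record(tweet_id=f"t{i}", followers=f)
            for i, f in enumerate([10, 10, 10, 10, 1000])
        ]
        exp = potential_exposure(recs, windows)
        assert exp.mean == 208
        assert exp.sd == pytest.approx(442.74145954, abs=1e-6)
        assert exp.mean_printed == 210  # 2 significant figures

    @given(factor=st.integers(1, 5))
    def test_scale_invariance(self, factor, windows):
        base = [10, 250, 3000]
        recs = lambda k: [
            make_record(tweet_id=f"t{i}", followers=f * k)
            for i, f in enumerate(base)
        ]
        e1 = potential_exposure(recs(1), windows)
        ek = potential_exposure(recs(factor), windows)
        assert (ek.series == e1.series * factor).all()
        assert ek.mean == pytest.approx(e1.mean * factor)


class TestFirstRetweetLatency:
    def test_latency_in_minutes(self):
        recs = [
            make_record(tweet_id="t1", when="2021-03-05T12:00:00"),
            make_record(
                tweet_id="r1", when="2021-03-05T12:02:18", source="t1",
                source_author="alice", author="bob",
            ),
        ]
        res = first_retweet_latency(recs)
        assert res.latencies["minutes"].tolist() == [2.3]
        assert res.median_minutes == 2.3

    def test_only_earliest_retweet_counts(self):
        recs = [
            make_record(tweet_id="t1", when="2021-03-05T12:00:00"),
            make_record(tweet_id="r2", when="2021-03-05T14:00:00", source="t1",
                        source_author="alice", author="bob"),
            make_record(tweet_id="r1", when="2021-03-05T12:30:00", source="t1",
                        source_author="alice", author="cara"),
        ]
        res = first_retweet_latency(recs)
        assert res.latencies["minutes"].tolist() == [30.0]

    def test_unretweeted_tweet_emits_no_latency(self):
        res = first_retweet_latency([make_record(tweet_id="t1")])
        assert res.n_originals == 1 and res.n_retweeted == 0
        assert res.latencies.empty and math.isnan(res.median_minutes)

    def test_retweet_before_source_rejected(self, caplog):
        recs = [
            make_record(tweet_id="t1", when="2021-03-05T12:00:00"),
            make_record(tweet_id="r1", when="2021-03-05T11:00:00", source="t1",
                        source_author="alice", author="bob"),
        ]
        with caplog.at_level("WARNING"):
            res = first_retweet_latency(recs)
        assert res.n_rejected_retweets == 1 and res.n_retweeted == 0

    def test_ecdf_definition(self):
        e = Ecdf([1.0, 2.0, 4.0])
        assert e(2.0) == pytest.approx(2 / 3)
        assert e(0.5) == 0.0
        assert e(4.0) == 1.0

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=50))
    def test_ecdf_monotone_bounded_reaches_one(self, sample):
        e = Ecdf(sample)
        grid = np.linspace(min(sample) - 1, max(sample) + 1, 40)
        vals = e(grid)
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 0) & (vals <= 1))
        assert e(max(sample)) == 1.0


class TestRetweetedFraction:
    def test_simple_quarter(self):
        recs = [make_record(tweet_id=f"t{i}") for i in range(4)]
        recs.append(
            make_record(tweet_id="r1", when="2021-03-05T13:00:00", source="t0",
                        source_author="alice", author="bob")
        )
        assert retweeted_fraction(recs) == 25.0

    def test_zero_retweets(self):
        recs = [make_record(tweet_id=f"t{i}") for i in range(5)]
        assert retweeted_fraction(recs) == 0.0

    def test_no_originals_is_undefined(self):
        assert math.isnan(retweeted_fraction([]))

    def test_recovers_binomial_probability(self, windows):
        # Binomial oracle: with per-tweet retweet probability p and n tweets,
        # the estimate should land within 3 SE of p.
        rng = np.random.default_rng(42)
        p, n = 0.15, 10_000
        recs = []
        for i in range(n):
            recs.append(make_record(tweet_id=f"t{i}", when="2021-03-05T10:00:00"))
            if rng.random() < p:
                recs.append(
                    make_record(tweet_id=f"r{i}", when="2021-03-05T11:00:00",
                                source=f"t{i}", source_author="alice", author="bob")
                )
        est = retweeted_fraction(recs, windows) / 100
        assert abs(est - p) <= 3 * math.sqrt(p * (1 - p) / n)


class TestRankTest:
    def test_identical_samples_not_significant(self):
        _, p = rank_test([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_separated_samples_significant(self):
        a = list(range(1, 51))
        b = list(range(51, 101))
        _, p = rank_test(a, b)
        assert p < 0.001
        # exact rank-sum oracle: complete separation gives U = 0 for a
        u, _ = rank_test(a, b)
        assert u in (0.0, 2500.0)  # U_a or U_b depending on orientation

    def test_kruskal_on_identical_samples_is_null(self):
        h, p = rank_test([1, 1, 1], [1, 1, 1], [1, 1, 1], method="kruskal_wallis")
        assert h == pytest.approx(0.0, abs=1e-9) and p >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1, 2])

    def test_mann_whitney_requires_two_samples(self):
        with pytest.raises(ValueError):
            rank_test([1], [2], [3], method="mann_whitney_u")
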
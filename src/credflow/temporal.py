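"""Temporal statistics: daily volume, potential exposure, propagation speed.

Potential exposure follows the follower-count proxy: the audience a tweet
could reach is approximated by its author's follower count, so a day's
potential exposure is the sum of follower counts over that day's records.
Propagation speed is the time from a tweet's posting to its earliest
observed retweet, summarised as an empirical CDF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_sig_half_up
from .records import PeriodWindows, TweetRecord

logger = logging.getLogger(__name__)


def _series_over_window(
    values: Mapping, windows: PeriodWindows, dtype=np.int64
) -> pd.Series:
    dates = windows.all_dates()
    s = pd.Series([values.get(d, 0) for d in dates], index=pd.Index(dates, name="date"))
    return s.astype(dtype)


def daily_volume(
    records: Iterable[TweetRecord],
    windows: PeriodWindows,
    *,
    originals_only: bool = False,
    scale: float = 1.0,
) -> pd.Series:
    """Records per UTC date over the whole study window (missing days = 0).

    Tweets and retweets both count unless ``originals_only``.  ``scale`` is a
    display-only multiplier recorded in ``series.attrs["scale"]``; stored
    values are never scaled.
    """
    counts: dict = {}
    for rec in records:
        if originals_only and rec.is_retweet:
            continue
        d = rec.created_at.date()
        if windows.assign(d) is not None:
            counts[d] = counts.get(d, 0) + 1
    s = _series_over_window(counts, windows)
    s.attrs["scale"] = scale
    return s


@dataclass
class ExposureSummary:
    """Daily potential-exposure series plus per-record follower statistics."""

    series: pd.Series
    mean: float
    sd: float

    @property
    def mean_printed(self) -> float:
        return round_sig_half_up(self.mean, 2)

    @property
    def sd_printed(self) -> float:
        return round_sig_half_up(self.sd, 2)


def potential_exposure(
    records: Iterable[TweetRecord],
    windows: PeriodWindows,
    *,
    originals_only: bool = False,
) -> ExposureSummary:
    """Daily sum of author follower counts, plus the per-record mean and SD.

    The mean and sample SD (printed at two significant figures) describe the
    audience-per-record distribution over the whole window.
    """
    sums: dict = {}
    followers: list[int] = []
    for rec in records:
        if originals_only and rec.is_retweet:
            continue
        d = rec.created_at.date()
        if windows.assign(d) is None:
            continue
        sums[d] = sums.get(d, 0) + rec.author_followers
        followers.append(rec.author_followers)
    series = _series_over_window(sums, windows)
    if followers:
        arr = np.asarray(followers, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        mean, sd = math.nan, math.nan
    return ExposureSummary(series=series, mean=mean, sd=sd)


class Ecdf:
    """Right-continuous empirical CDF of a sample."""

    def __init__(self, sample: Sequence[float]):
        arr = np.sort(np.asarray(sample, dtype=float))
        if arr.size == 0:
            raise ValueError("ECDF requires a non-empty sample")
        self.points = arr
        self.n = arr.size

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        out = np.searchsorted(self.points, t_arr, side="right") / self.n
        return float(out) if np.isscalar(t) else out

    def as_frame(self) -> pd.DataFrame:
        """Unique sample points and their cumulative probabilities."""
        xs, counts = np.unique(self.points, return_counts=True)
        return pd.DataFrame({"x": xs, "cdf": np.cumsum(counts) / self.n})


@dataclass
class LatencyResult:
    """First-retweet latencies (minutes) and the derived ECDF."""

    latencies: pd.DataFrame  # columns: tweet_id, minutes
    n_originals: int
    n_retweeted: int
    n_rejected_retweets: int

    @property
    def ecdf(self) -> Ecdf:
        return Ecdf(self.latencies["minutes"].to_numpy())

    @property
    def median_minutes(self) -> float:
        if self.latencies.empty:
            return math.nan
        return float(self.latencies["minutes"].median())


def first_retweet_latency(records: Iterable[TweetRecord]) -> LatencyResult:
    """Minutes from each original tweet to its earliest observed retweet.

    Originals with no retweet in the stream contribute no latency (they
    still count in ``n_originals``).  A retweet stamped earlier than its
    source tweet is rejected with a data-integrity warning.
    """
    records = list(records)
    originals = {rec.tweet_id: rec for rec in records if not rec.is_retweet}
    earliest: dict[str, TweetRecord] = {}
    n_rejected = 0
    for rec in records:
        if not rec.is_retweet:
            continue
        src = originals.get(rec.source_tweet_id)
        if src is None:
            continue
        if rec.created_at < src.created_at:
            n_rejected += 1
            logger.warning(
                "retweet %s predates its source tweet %s; rejected",
                rec.tweet_id,
                src.tweet_id,
            )
            continue
        cur = earliest.get(src.tweet_id)
        if cur is None or rec.created_at < cur.created_at:
            earliest[src.tweet_id] = rec
    rows = [
        {
            "tweet_id": tid,
            "minutes": (rt.created_at - originals[tid].created_at).total_seconds() / 60.0,
        }
        for tid, rt in sorted(earliest.items())
    ]
    latencies = pd.DataFrame(rows, columns=["tweet_id", "minutes"])
    return LatencyResult(
        latencies=latencies,
        n_originals=len(originals),
        n_retweeted=len(earliest),
        n_rejected_retweets=n_rejected,
    )


def retweeted_fraction(
    records: Iterable[TweetRecord], windows: PeriodWindows | None = None
) -> float:
    """Percentage of original tweets retweeted within the study window.

    Counts an original as retweeted when at least one retweet of it appears
    in the stream (inside ``windows`` when given).  Returned at three
    significant figures, half-up; NaN when there are no originals.
    """
    records = list(records)
    if windows is not None:
        records = [r for r in records if windows.assign(r.created_at) is not None]
    originals = {r.tweet_id for r in records if not r.is_retweet}
    if not originals:
        return math.nan
    retweeted = {
        r.source_tweet_id
        for r in records
        if r.is_retweet and r.source_tweet_id in originals
    }
    return round_sig_half_up(100.0 * len(retweeted) / len(originals), 3)


def rank_test(*samples: Sequence[float], method: str = "mann_whitney_u"):
    """Two-sided rank test with tie correction.

    ``mann_whitney_u`` takes exactly two samples; ``kruskal_wallis`` takes
    two or more.  Returns ``(statistic, pvalue)``.  The 0.05 significance
    threshold is the caller's concern.
    """
    if any(len(s) == 0 for s in samples):
        raise ValueError("all samples must be non-empty")
    if method == "mann_whitney_u":
        if len(samples) != 2:
            raise ValueError("mann_whitney_u requires exactly two samples")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif method == "kruskal_wallis":
        if len(samples) < 2:
            raise ValueError("kruskal_wallis requires at least two samples")
        pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
        if np.all(pooled == pooled[0]):
            # Degenerate case scipy refuses: no rank variation at all.
            return 0.0, 1.0
        res = stats.kruskal(*samples)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
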
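"""Synthetic tweet-stream generator with closed-form ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: lognormal (heavy-tailed) follower counts; account-creation dates
with a pandemic-era spike; per-user Poisson posting with an on-topic rate
shock inside the peak news window; URL attachment with a configurable
low-credibility share (elevated for on-topic posts during the peak);
and broadcast retweet cascades — every retweet is attributed directly to
the original author, because the flattened sharing model cannot represent
intermediary chains — with lognormal retweet delays and a follower-count-
driven retweet intensity.  One "corporate outlet" hub account can be
planted with the largest audience, an elevated posting rate, and a boosted
retweet rate, and one low-credibility outlet domain carries a dominant
share of the low-credibility URL pool; both give the influence rankings a
known right answer.

Every expectation the pipeline estimates (per-period volume, the
low-credibility URL shares, the retweeted fraction including end-of-window
censoring of late retweets) is available in closed form from
:func:`expected_statistics`, so the whole analysis can be tested as an
estimator of the generator's parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import classify_record, compile_keyword_matcher, CredClass
from .records import PeriodWindows, TweetRecord
from .temporal import retweeted_fraction as _retweeted_fraction

#: Keywords every generated record matches (the stream is keyword-collected).
DEFAULT_STREAM_KEYWORDS = ("covid", "coronavirus", "vaccine", "pandemic", "icu")
#: Keywords marking the topic (vaccine-scare) sub-corpus.
DEFAULT_TOPIC_KEYWORDS = ("astrazeneca",)


def _default_lowcred_pool() -> dict[str, float]:
    # One dominant planted outlet at 40% of the pool weight, eight minor ones.
    pool = {"globalwire-tonight.com": 0.40}
    for name in (
        "healthtruthpress.org",
        "thepatriotbeacon.com",
        "alt-news-daily.net",
        "viralclaimshub.com",
        "sunrise-dispatch.info",
        "freedomfactsnow.org",
        "rumorline.net",
        "plandemicpost.com",
    ):
        pool[name] = 0.075
    return pool


def _default_credible_pool() -> dict[str, float]:
    return {
        name: 1.0
        for name in (
            "examplenews.org",
            "city-herald.com",
            "sciencedeskdaily.org",
            "publichealth-bulletin.org",
            "worldtimes-online.com",
            "metro-observer.net",
        )
    }


@dataclass
class SimConfig:
    """Generative parameters for a synthetic keyword-collected tweet stream."""

    n_users: int = 2000
    # Follower counts ~ floor(lognormal); median e^mu (~200 followers).
    follower_mu: float = math.log(200.0)
    follower_sigma: float = 2.0
    verified_base_prob: float = 0.008
    # Extra verification probability per decade of followers above 10^4.
    verified_follower_boost: float = 0.10
    # Account-creation dates: a spike since the pandemic declaration,
    # uniform back to the platform's early years otherwise.
    creation_spike_weight: float = 0.25
    creation_spike_start: date = date(2020, 3, 11)
    account_epoch: date = date(2007, 1, 1)
    windows: PeriodWindows = field(default_factory=PeriodWindows.march_2021_study)
    peak_label: str = "Peak"
    base_rate: float = 1.0  # original tweets per user per day
    topic_share: float = 0.05  # fraction of posting on-topic
    peak_multiplier: float = 2.5  # on-topic rate multiplier inside the peak
    p_url: float = 0.145  # probability a tweet carries a URL
    p_lc_base: float = 0.019  # low-credibility share of URL tweets, baseline
    p_lc_peak: float = 0.029  # ... for on-topic tweets inside the peak
    lowcred_pool: dict[str, float] = field(default_factory=_default_lowcred_pool)
    credible_pool: dict[str, float] = field(default_factory=_default_credible_pool)
    # Expected retweets per tweet: scale * (1+followers)^exponent.
    retweet_rate_scale: float = 0.04
    retweet_follower_exponent: float = 0.25
    # First-retweet delays ~ lognormal, minutes; median e^mu (~10 min).
    delay_log_mu: float = math.log(10.0)
    delay_log_sigma: float = 2.0
    hub_enabled: bool = True
    hub_followers: int = 5_000_000
    hub_rate_multiplier: float = 5.0  # hub posts this multiple of base_rate
    hub_retweet_boost: float = 25.0  # multiplies the hub's retweet intensity
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in (
            "verified_base_prob",
            "creation_spike_weight",
            "topic_share",
            "p_url",
            "p_lc_base",
            "p_lc_peak",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} not in [0, 1]")
        for name in ("base_rate", "peak_multiplier"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.n_users < 2:
            problems.append("n_users must be >= 2")
        if not self.lowcred_pool or not self.credible_pool:
            problems.append("domain pools must be non-empty")
        if set(self.lowcred_pool) & set(self.credible_pool):
            problems.append("domain pools must be disjoint")
        if any(w <= 0 for w in self.lowcred_pool.values()) or any(
            w <= 0 for w in self.credible_pool.values()
        ):
            problems.append("pool weights must be positive")
        if self.retweet_rate_scale < 0:
            problems.append("retweet_rate_scale must be >= 0")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def planted_domain(self) -> str:
        return max(self.lowcred_pool, key=lambda d: (self.lowcred_pool[d], d))

    @property
    def hub_user_id(self) -> str | None:
        return "u000000" if self.hub_enabled else None


@dataclass
class GroundTruth:
    """Closed-form expectations implied by a :class:`SimConfig`."""

    expected_originals: dict[str, float]
    lc_share_base: float
    lc_share_peak_on_topic: float
    expected_retweeted_fraction_pct: float
    topic_share: float
    peak_multiplier: float
    planted_domain: str
    hub_user_id: str | None
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def generate_users(config: SimConfig) -> pd.DataFrame:
    """User table (user_id, followers, verified, created_at, is_hub).

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    followers = np.floor(
        rng.lognormal(config.follower_mu, config.follower_sigma, size=n)
    ).astype(np.int64)
    decades_above = np.maximum(0.0, np.log10(followers + 1.0) - 4.0)
    p_verified = np.clip(
        config.verified_base_prob + config.verified_follower_boost * decades_above,
        0.0,
        1.0,
    )
    verified = rng.random(n) < p_verified
    spike = rng.random(n) < config.creation_spike_weight
    pre_days = (config.creation_spike_start - config.account_epoch).days
    spike_days = (config.windows.start - config.creation_spike_start).days
    offsets = np.where(
        spike,
        pre_days + rng.integers(0, max(spike_days, 1), size=n),
        rng.integers(0, max(pre_days, 1), size=n),
    )
    created = [config.account_epoch + timedelta(days=int(o)) for o in offsets]
    users = pd.DataFrame(
        {
            "user_id": [f"u{i:06d}" for i in range(n)],
            "followers": followers,
            "verified": verified,
            "created_at": created,
            "is_hub": False,
        }
    )
    if config.hub_enabled:
        hub_followers = max(config.hub_followers, int(followers.max()) + 1)
        users.loc[0, "followers"] = hub_followers
        users.loc[0, "verified"] = True
        users.loc[0, "is_hub"] = True
        users.loc[0, "created_at"] = date(2009, 6, 1)
    return users


def _daily_topic_rates(
    users: pd.DataFrame, config: SimConfig, day: date
) -> tuple[np.ndarray, np.ndarray]:
    """Per-user expected on-topic and off-topic original tweets for one day."""
    n = len(users)
    is_peak = config.windows.assign(day) == config.peak_label
    mult = config.peak_multiplier if is_peak else 1.0
    on = np.full(n, config.base_rate * config.topic_share * mult)
    off = np.full(n, config.base_rate * (1.0 - config.topic_share))
    if config.hub_enabled:
        hub = users["is_hub"].to_numpy()
        # The planted outlet posts only on-topic, at an elevated rate that
        # follows the same peak shock as everyone else's on-topic posting.
        on[hub] = config.base_rate * config.hub_rate_multiplier * mult
        off[hub] = 0.0
    return on, off


def _retweet_lambda(users: pd.DataFrame, config: SimConfig) -> np.ndarray:
    lam = config.retweet_rate_scale * np.power(
        1.0 + users["followers"].to_numpy(dtype=float),
        config.retweet_follower_exponent,
    )
    if config.hub_enabled:
        lam[users["is_hub"].to_numpy()] *= config.hub_retweet_boost
    return lam


def _draw_domain(rng, pool: Mapping[str, float]) -> str:
    names = sorted(pool)
    weights = np.array([pool[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def generate_stream(
    users: pd.DataFrame, config: SimConfig
) -> tuple[list[TweetRecord], GroundTruth]:
    """Generate a full study-window stream of tweets and retweets.

    Output is chronologically sorted and round-trips through the JSON-Lines
    reader.  Retweets falling past the study end are censored (dropped),
    exactly as a fixed collection window would censor them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    end_dt = datetime.combine(
        config.windows.end + timedelta(days=1), datetime.min.time(), tzinfo=timezone.utc
    )
    follower_arr = users["followers"].to_numpy()
    verified_arr = users["verified"].to_numpy()
    created_arr = list(users["created_at"])
    ids = list(users["user_id"])
    lam = _retweet_lambda(users, config)
    n_users = len(users)
    records: list[TweetRecord] = []
    tweet_counter = 0
    rt_counter = 0

    for day in config.windows.all_dates():
        day_start = datetime.combine(day, datetime.min.time(), tzinfo=timezone.utc)
        is_peak = config.windows.assign(day) == config.peak_label
        on_rate, off_rate = _daily_topic_rates(users, config, day)
        n_on = rng.poisson(on_rate)
        n_off = rng.poisson(off_rate)
        for on_topic, counts in ((True, n_on), (False, n_off)):
            posting_users = np.repeat(np.arange(n_users), counts)
            seconds = rng.integers(0, 86400, size=posting_users.size)
            for uidx, sec in zip(posting_users, seconds):
                tweet_counter += 1
                tid = f"t{tweet_counter:07d}"
                t_post = day_start + timedelta(seconds=int(sec))
                if on_topic:
                    text = f"astrazeneca vaccine report {tweet_counter}"
                else:
                    text = f"covid briefing {tweet_counter}"
                urls: tuple[str, ...] = ()
                if rng.random() < config.p_url:
                    p_lc = (
                        config.p_lc_peak
                        if (on_topic and is_peak)
                        else config.p_lc_base
                    )
                    if rng.random() < p_lc:
                        # The hub models the dominant outlet's corporate
                        # account: its low-credibility links self-promote
                        # the outlet's own domain.
                        if config.hub_enabled and uidx == 0:
                            domain = config.planted_domain
                        else:
                            domain = _draw_domain(rng, config.lowcred_pool)
                    else:
                        domain = _draw_domain(rng, config.credible_pool)
                    urls = (f"https://{domain}/p/{tid}",)
                author = ids[uidx]
                records.append(
                    TweetRecord(
                        tweet_id=tid,
                        created_at=t_post,
                        author_id=author,
                        author_followers=int(follower_arr[uidx]),
                        author_verified=bool(verified_arr[uidx]),
                        author_created_at=created_arr[uidx],
                        text=text,
                        urls=urls,
                    )
                )
                # Broadcast cascade: retweets attach straight to the author.
                n_rt = rng.poisson(lam[uidx])
                if n_rt == 0:
                    continue
                delays = rng.lognormal(
                    config.delay_log_mu, config.delay_log_sigma, size=n_rt
                )
                for delay_min in delays:
                    # second resolution, matching the on-disk schema
                    rt_time = (t_post + timedelta(minutes=float(delay_min))).replace(
                        microsecond=0
                    )
                    if rt_time >= end_dt:
                        continue
                    ridx = int(rng.integers(0, n_users - 1))
                    if ridx >= uidx:
                        ridx += 1
                    rt_counter += 1
                    records.append(
                        TweetRecord(
                            tweet_id=f"r{rt_counter:07d}",
                            created_at=rt_time,
                            author_id=ids[ridx],
                            author_followers=int(follower_arr[ridx]),
                            author_verified=bool(verified_arr[ridx]),
                            author_created_at=created_arr[ridx],
                            text=f"RT @{author}: {text}",
                            urls=urls,
                            source_tweet_id=tid,
                            source_author_id=author,
                        )
                    )
    records.sort(key=lambda r: (r.created_at, r.tweet_id))
    return records, expected_statistics(config, users)


def expected_statistics(
    config: SimConfig, users: pd.DataFrame | None = None
) -> GroundTruth:
    """Closed-form expectations implied by the config.

    The expected retweeted fraction accounts for end-of-window censoring:
    a tweet posted at time t is retweeted-within-window with probability
    1 - exp(-lambda_u * F(T_end - t)), F the lognormal delay CDF, averaged
    over the posting-rate-weighted distribution of (user, posting time)
    with a four-point quadrature within each day.
    """
    config.validate()
    if users is None:
        users = generate_users(config)
    days = config.windows.all_dates()
    expected: dict[str, float] = {}
    rate_mat = np.zeros((len(users), len(days)))
    for j, day in enumerate(days):
        on, off = _daily_topic_rates(users, config, day)
        total = on + off
        rate_mat[:, j] = total
        label = config.windows.assign(day)
        expected[label] = expected.get(label, 0.0) + float(total.sum())

    lam = _retweet_lambda(users, config)
    end_dt = datetime.combine(
        config.windows.end + timedelta(days=1), datetime.min.time(), tzinfo=timezone.utc
    )
    quad = np.array([0.125, 0.375, 0.625, 0.875])
    # remaining minutes to window end for each (day, quadrature point)
    rem = np.empty((len(days), quad.size))
    for j, day in enumerate(days):
        day_start = datetime.combine(day, datetime.min.time(), tzinfo=timezone.utc)
        for q, f in enumerate(quad):
            rem[j, q] = (end_dt - (day_start + timedelta(days=float(f)))).total_seconds() / 60.0
    cdf = stats.lognorm.cdf(
        rem, s=config.delay_log_sigma, scale=math.exp(config.delay_log_mu)
    )
    # P(>=1 in-window retweet) per (user, day, quadrature point)
    p_rt = 1.0 - np.exp(-lam[:, None, None] * cdf[None, :, :])
    weights = rate_mat[:, :, None] / 4.0
    frac = float((weights * p_rt).sum() / rate_mat.sum())

    return GroundTruth(
        expected_originals={k: float(v) for k, v in expected.items()},
        lc_share_base=config.p_lc_base,
        lc_share_peak_on_topic=config.p_lc_peak,
        expected_retweeted_fraction_pct=100.0 * frac,
        topic_share=config.topic_share,
        peak_multiplier=config.peak_multiplier,
        planted_domain=config.planted_domain,
        hub_user_id=config.hub_user_id,
        seed=config.seed,
    )


def recover_parameters(
    records: Sequence[TweetRecord],
    windows: PeriodWindows,
    lowcred_domains: Iterable[str],
    topic_keywords: Sequence[str] = DEFAULT_TOPIC_KEYWORDS,
    peak_label: str = "Peak",
) -> dict[str, tuple[float, float]]:
    """Estimate generator parameters from a stream via the analysis pipeline.

    Returns ``{name: (estimate, standard_error)}`` for the on-topic peak
    rate multiplier, the two low-credibility URL shares, and the retweeted
    fraction (as a proportion).  The pipeline is thereby used as an
    estimator of the generative parameters.
    """
    lowcred = frozenset(d.lower() for d in lowcred_domains)
    is_topic = compile_keyword_matcher(topic_keywords)
    originals = [
        r
        for r in records
        if not r.is_retweet and windows.assign(r.created_at) is not None
    ]
    days_peak = windows.n_days(peak_label)
    days_off = sum(windows.n_days(lab) for lab in windows.labels) - days_peak

    on_topic = [is_topic(r.text) for r in originals]
    in_peak = [windows.assign(r.created_at) == peak_label for r in originals]
    n_peak_t = sum(1 for t, p in zip(on_topic, in_peak) if t and p)
    n_off_t = sum(1 for t, p in zip(on_topic, in_peak) if t and not p)
    out: dict[str, tuple[float, float]] = {}
    if n_peak_t and n_off_t:
        mult = (n_peak_t / days_peak) / (n_off_t / days_off)
        se = mult * math.sqrt(1.0 / n_peak_t + 1.0 / n_off_t)
        out["peak_multiplier"] = (mult, se)
    else:
        out["peak_multiplier"] = (math.nan, math.nan)

    def _share(subset: list[TweetRecord]) -> tuple[float, float]:
        urled = [r for r in subset if r.urls]
        if not urled:
            return math.nan, math.nan
        k = sum(1 for r in urled if classify_record(r, lowcred) is CredClass.LOW_CREDIBILITY)
        p = k / len(urled)
        return p, math.sqrt(max(p * (1 - p), 1e-12) / len(urled))

    out["p_lc_peak"] = _share(
        [r for r, t, p in zip(originals, on_topic, in_peak) if t and p]
    )
    out["p_lc_base"] = _share(
        [r for r, t, p in zip(originals, on_topic, in_peak) if not (t and p)]
    )

    frac_pct = _retweeted_fraction(records, windows)
    p = frac_pct / 100.0
    se = math.sqrt(max(p * (1 - p), 1e-12) / max(len(originals), 1))
    out["retweeted_fraction"] = (p, se)
    return out
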
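"""Influential domains and authors, and account-property profiles.

Domain popularity counts how often each low-credibility registered domain
was tweeted or retweeted per period; author influence is out-degree
centrality (distinct retweeters, whole-graph normalized) summed across the
period graphs; account profiles compare verification, account age, and
audience size across user cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rounding import round_sig_half_up
from .corpus import CorpusPartition, CredClass, record_domains
from .network import NodeClass, degree_centrality
from .records import TweetRecord
from .temporal import rank_test

#: Default account-age cutoff: the WHO pandemic declaration date.
DEFAULT_CREATION_CUTOFF = date(2020, 3, 11)


def domain_popularity(
    partition: CorpusPartition,
    threshold: int,
    *,
    cls: CredClass = CredClass.LOW_CREDIBILITY,
) -> pd.DataFrame:
    """Per-period reference counts for domains popular in at least one period.

    Each record (tweet or retweet) contributes one count to every distinct
    registered domain it references.  A domain is retained iff its count
    reaches ``threshold`` in at least one period; rows are ordered by total
    count descending, ties broken lexicographically by domain.
    Returns tidy columns (domain, period, count).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    periods = list(partition.windows.labels)
    counts: dict[str, dict[str, int]] = {}
    for period in periods:
        for rec in partition.records(period=period, cls=cls):
            for dom in record_domains(rec):
                counts.setdefault(dom, dict.fromkeys(periods, 0))[period] += 1
    retained = [
        dom for dom, per in counts.items() if max(per.values(), default=0) >= threshold
    ]
    retained.sort(key=lambda d: (-sum(counts[d].values()), d))
    rows = [
        {"domain": dom, "period": period, "count": counts[dom][period]}
        for dom in retained
        for period in periods
    ]
    return pd.DataFrame(rows, columns=["domain", "period", "count"])


def top_authors(
    graphs: Mapping[str, nx.DiGraph], k: int = 100
) -> pd.DataFrame:
    """Top-k users by out-degree centrality summed across period graphs.

    A user absent from a period contributes 0 for that period.  Ties break
    by total retweets received (node weight w), then user id; users with an
    all-zero sum are never ranked.  Returns columns (user_id, total_score,
    total_w, <score per period>), at most ``k`` rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_period: dict[str, dict[str, float]] = {}
    total_w: dict[str, int] = {}
    for label, G in graphs.items():
        scores = degree_centrality(G, "out") if G.number_of_nodes() >= 2 else {}
        per_period[label] = scores
        for u in G.nodes:
            total_w[u] = total_w.get(u, 0) + G.nodes[u].get("w", 0)
    users = set().union(*(set(s) for s in per_period.values())) if per_period else set()
    summed = {
        u: sum(per_period[label].get(u, 0.0) for label in per_period) for u in users
    }
    ranked = [u for u in users if summed[u] > 0]
    if not ranked:
        warnings.warn("all summed out-degree centralities are zero; empty ranking")
        cols = ["user_id", "total_score", "total_w", *per_period]
        return pd.DataFrame(columns=cols)
    ranked.sort(key=lambda u: (-summed[u], -total_w.get(u, 0), u))
    ranked = ranked[:k]
    rows = [
        {
            "user_id": u,
            "total_score": summed[u],
            "total_w": total_w.get(u, 0),
            **{label: per_period[label].get(u, 0.0) for label in per_period},
        }
        for u in ranked
    ]
    return pd.DataFrame(rows)


def user_table(records: Iterable[TweetRecord]) -> pd.DataFrame:
    """One row per distinct user seen in the records (first sighting wins)."""
    seen: dict[str, dict] = {}
    for rec in records:
        if rec.author_id not in seen:
            seen[rec.author_id] = {
                "user_id": rec.author_id,
                "followers": rec.author_followers,
                "verified": rec.author_verified,
                "created_at": rec.author_created_at,
            }
    return pd.DataFrame(
        sorted(seen.values(), key=lambda r: r["user_id"]),
        columns=["user_id", "followers", "verified", "created_at"],
    )


def authors_cohort(
    users: pd.DataFrame,
    node_classes: Mapping[str, NodeClass],
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Users classified Author (and, unless ``strict``, Author/Sharer)."""
    wanted = {NodeClass.AUTHOR} if strict else {NodeClass.AUTHOR, NodeClass.AUTHOR_SHARER}
    ids = {u for u, c in node_classes.items() if c in wanted}
    return users[users["user_id"].isin(ids)].reset_index(drop=True)


@dataclass
class AccountProfile:
    """Summary of one cohort's account properties."""

    cohort: str
    n: int
    verified_pct: float
    creation_year_hist: pd.Series
    share_since_cutoff_pct: float
    follower_median: float
    follower_log_hist: pd.Series


def _profile(name: str, users: pd.DataFrame, cutoff: date) -> AccountProfile:
    if users.empty:
        raise ValueError(f"cohort {name!r} is empty")
    n = len(users)
    verified_pct = round_sig_half_up(100.0 * users["verified"].sum() / n, 2)
    created = pd.Series([d.year for d in users["created_at"]])
    year_hist = created.value_counts().sort_index()
    since = sum(1 for d in users["created_at"] if d >= cutoff)
    followers = users["followers"].to_numpy(dtype=float)
    # Log-decade bins: 0, 1-9, 10-99, ... (zero-follower accounts first bin).
    edges = [-0.5] + [10**i - 0.5 for i in range(8)] + [math.inf]
    log_hist = pd.Series(
        np.histogram(followers, bins=edges)[0],
        index=["0", "1-9", "10-99", "100-999", "1k-10k", "10k-100k",
               "100k-1M", "1M-10M", ">=10M"],
    )
    return AccountProfile(
        cohort=name,
        n=n,
        verified_pct=verified_pct,
        creation_year_hist=year_hist,
        share_since_cutoff_pct=round_sig_half_up(100.0 * since / n, 3),
        follower_median=float(np.median(followers)),
        follower_log_hist=log_hist,
    )


def account_profiles(
    cohorts: Mapping[str, pd.DataFrame],
    *,
    cutoff: date = DEFAULT_CREATION_CUTOFF,
) -> tuple[dict[str, AccountProfile], pd.DataFrame]:
    """Profile each cohort and rank-test every cohort pair.

    ``cohorts`` maps name -> user table (columns user_id, followers,
    verified, created_at).  Returns the per-cohort profiles plus a tidy
    frame of pairwise Mann-Whitney tests on account-creation dates and
    follower counts.
    """
    profiles = {name: _profile(name, users, cutoff) for name, users in cohorts.items()}
    tests = []
    names = list(cohorts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for prop, getter in (
                ("created_at", lambda u: [d.toordinal() for d in u["created_at"]]),
                ("followers", lambda u: u["followers"].tolist()),
            ):
                stat, p = rank_test(getter(cohorts[a]), getter(cohorts[b]))
                tests.append(
                    {"cohort_a": a, "cohort_b": b, "property": prop,
                     "statistic": stat, "pvalue": p}
                )
    return profiles, pd.DataFrame(
        tests, columns=["cohort_a", "cohort_b", "property", "statistic", "pvalue"]
    )
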
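"""Corpus construction: keyword filtering, credibility partition, summaries.

The analysis splits a keyword-collected tweet stream three ways per study
period: records linking at least one low-credibility domain (proxied
misinformation), records with URLs but no listed domain (the residual
dataset), and records with no URL at all.  The three classes are disjoint
and exhaustive within each period.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from ._rounding import round_half_up, round_sig_half_up
from .domains import INVALID_DOMAIN, normalize_domain
from .records import PeriodWindows, TweetRecord

logger = logging.getLogger(__name__)


class CredClass(str, Enum):
    """Credibility class of a record within its period."""

    LOW_CREDIBILITY = "low_credibility"
    RESIDUAL = "residual"
    NO_URL = "no_url"


def _is_spaced_script(keyword: str) -> bool:
    # Word-boundary matching only makes sense for scripts that delimit words;
    # treat a keyword as "spaced" when all its letters are Latin.
    for ch in keyword:
        if ch.isalpha():
            try:
                if not unicodedata.name(ch).startswith("LATIN"):
                    return False
            except ValueError:
                return False
    return True


def _normalize_text(text: str) -> str:
    return unicodedata.normalize("NFKC", text).casefold()


def compile_keyword_matcher(keywords: Sequence[str]):
    """Build a predicate text -> bool for case-insensitive keyword matching.

    Latin-script keywords match on word boundaries ("vaccine" does not hit
    "vaccinate", but "icu" does hit "Elite ICU"); keywords in non-spaced
    scripts match as raw substrings.  Text and keywords are NFKC-normalized
    and casefolded first.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    boundary_patterns = []
    substrings = []
    for kw in keywords:
        norm = _normalize_text(kw.strip())
        if not norm:
            continue
        if _is_spaced_script(norm):
            boundary_patterns.append(r"(?<!\w)" + re.escape(norm) + r"(?!\w)")
        else:
            substrings.append(norm)
    if not boundary_patterns and not substrings:
        raise ValueError("keyword list contains no usable keywords")
    regex = re.compile("|".join(boundary_patterns)) if boundary_patterns else None

    def matches(text: str) -> bool:
        norm = _normalize_text(text)
        if regex is not None and regex.search(norm):
            return True
        return any(s in norm for s in substrings)

    return matches


def filter_keywords(
    records: Iterable[TweetRecord], keywords: Sequence[str]
) -> list[TweetRecord]:
    """Keep records whose own text contains at least one keyword."""
    matches = compile_keyword_matcher(keywords)
    return [rec for rec in records if matches(rec.text)]


@dataclass
class CorpusPartition:
    """Per-(period, credibility class) record sets for one corpus."""

    windows: PeriodWindows
    by_period_class: dict[tuple[str, CredClass], list[TweetRecord]]
    n_outside_windows: int = 0
    topic: bool = False

    def records(
        self, period: str | None = None, cls: CredClass | None = None
    ) -> list[TweetRecord]:
        out: list[TweetRecord] = []
        for (per, c), recs in self.by_period_class.items():
            if period is not None and per != period:
                continue
            if cls is not None and c != cls:
                continue
            out.extend(recs)
        return out

    def count(self, period: str | None = None, cls: CredClass | None = None) -> int:
        return len(self.records(period, cls))

    def counts_table(self) -> pd.DataFrame:
        rows = []
        for per in self.windows.labels:
            row = {"period": per}
            for c in CredClass:
                row[c.value] = self.count(per, c)
            row["total"] = sum(row[c.value] for c in CredClass)
            rows.append(row)
        return pd.DataFrame(rows)


def record_domains(record: TweetRecord) -> set[str]:
    """Distinct valid registered domains referenced by a record."""
    doms = {normalize_domain(u) for u in record.urls}
    doms.discard(INVALID_DOMAIN)
    return doms


def classify_record(record: TweetRecord, lowcred_domains: frozenset[str] | set[str]) -> CredClass:
    if not record.urls:
        return CredClass.NO_URL
    # Any listed URL makes the record low-credibility; unparseable URLs
    # still count toward URL presence but never match the list.
    if record_domains(record) & set(lowcred_domains):
        return CredClass.LOW_CREDIBILITY
    return CredClass.RESIDUAL


def partition_credibility(
    records: Iterable[TweetRecord],
    lowcred_domains: Iterable[str],
    windows: PeriodWindows,
    *,
    topic: bool = False,
) -> CorpusPartition:
    """Split records by period window and credibility class.

    Records whose date falls outside every window are dropped and counted in
    ``n_outside_windows``.
    """
    lowcred = frozenset(d.lower() for d in lowcred_domains)
    if not lowcred:
        raise ValueError("low-credibility domain list must be non-empty")
    by: dict[tuple[str, CredClass], list[TweetRecord]] = {}
    n_outside = 0
    for rec in records:
        period = windows.assign(rec.created_at)
        if period is None:
            n_outside += 1
            continue
        cls = classify_record(rec, lowcred)
        by.setdefault((period, cls), []).append(rec)
    if n_outside:
        logger.info("%d record(s) outside all study windows dropped", n_outside)
    return CorpusPartition(
        windows=windows, by_period_class=by, n_outside_windows=n_outside, topic=topic
    )


@dataclass(frozen=True)
class CorpusCounts:
    """Headline counts for one corpus."""

    total: int
    with_url: int
    low_credibility: int

    @classmethod
    def from_partition(cls, partition: CorpusPartition) -> "CorpusCounts":
        lc = partition.count(cls=CredClass.LOW_CREDIBILITY)
        residual = partition.count(cls=CredClass.RESIDUAL)
        total = lc + residual + partition.count(cls=CredClass.NO_URL)
        return cls(total=total, with_url=lc + residual, low_credibility=lc)


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else math.nan


def summarize_counts(
    full: CorpusCounts, topic: CorpusCounts | None = None
) -> pd.DataFrame:
    """Headline proportions, unrounded and at printed precision.

    Share-of-corpus percentages (URL share, topic share of the full corpus)
    print at one decimal; low-credibility shares print at two significant
    figures.  All rounding is half-up.  Zero denominators yield NaN, never a
    fake 0.
    """
    rows = []
    for name, counts in (("full", full), ("topic", topic)):
        if counts is None:
            continue
        url_pct = _pct(counts.with_url, counts.total)
        lc_of_total = _pct(counts.low_credibility, counts.total)
        lc_of_url = _pct(counts.low_credibility, counts.with_url)
        row = {
            "corpus": name,
            "total": counts.total,
            "with_url": counts.with_url,
            "low_credibility": counts.low_credibility,
            "url_pct": url_pct,
            "url_pct_printed": round_half_up(url_pct, 1),
            "lc_pct_of_total": lc_of_total,
            "lc_pct_of_total_printed": round_sig_half_up(lc_of_total, 2),
            "lc_pct_of_url": lc_of_url,
            "lc_pct_of_url_printed": round_sig_half_up(lc_of_url, 2),
        }
        if name == "topic":
            share = _pct(counts.total, full.total)
            row["share_of_full_pct"] = share
            row["share_of_full_pct_printed"] = round_half_up(share, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def corpus_summary(
    partition: CorpusPartition, topic_partition: CorpusPartition | None = None
) -> pd.DataFrame:
    """Summarize a built partition (and optional nested topic sub-corpus)."""
    full = CorpusCounts.from_partition(partition)
    topic = (
        CorpusCounts.from_partition(topic_partition)
        if topic_partition is not None
        else None
    )
    return summarize_counts(full, topic)
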
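"""Tweet records, study-period windows, and JSON-Lines stream I/O.

A stream is a JSON-Lines file with one object per posted tweet or retweet.
Field names (the on-disk schema):

``tweet_id``            opaque unique string
``created_at``          posting time, ISO-8601 UTC, second resolution
``author_id``           opaque user id string
``author_followers``    non-negative integer follower count
``author_verified``     boolean platform-verification flag
``author_created_at``   account creation date, ISO-8601 date
``source_tweet_id``     original tweet id (present iff the record is a retweet)
``source_author_id``    original author id (present iff the record is a retweet)
``urls``                list of absolute, already-expanded URL strings
``text``                unicode tweet text
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_MANDATORY_FIELDS = (
    "tweet_id",
    "created_at",
    "author_id",
    "author_followers",
    "author_verified",
    "author_created_at",
    "text",
)


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One posted tweet or retweet with its author metadata and URLs."""

    tweet_id: str
    created_at: datetime
    author_id: str
    author_followers: int
    author_verified: bool
    author_created_at: date
    text: str
    urls: tuple[str, ...] = ()
    source_tweet_id: str | None = None
    source_author_id: str | None = None

    def __post_init__(self) -> None:
        if (self.source_tweet_id is None) != (self.source_author_id is None):
            raise ValueError(
                "source_tweet_id and source_author_id must both be present "
                "or both be absent"
            )
        if self.author_followers < 0:
            raise ValueError("author_followers must be >= 0")
        if self.created_at.date() < self.author_created_at:
            raise ValueError("record predates its author's account creation")

    @property
    def is_retweet(self) -> bool:
        return self.source_tweet_id is not None

    def to_json_obj(self) -> dict:
        obj = {
            "tweet_id": self.tweet_id,
            "created_at": self.created_at.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "author_id": self.author_id,
            "author_followers": int(self.author_followers),
            "author_verified": bool(self.author_verified),
            "author_created_at": self.author_created_at.isoformat(),
            "urls": list(self.urls),
            "text": self.text,
        }
        if self.is_retweet:
            obj["source_tweet_id"] = self.source_tweet_id
            obj["source_author_id"] = self.source_author_id
        return obj

    @classmethod
    def from_json_obj(cls, obj: dict) -> "TweetRecord":
        for name in _MANDATORY_FIELDS:
            if name not in obj:
                raise KeyError(f"missing mandatory field {name!r}")
        created = _parse_timestamp(obj["created_at"])
        acct_created = date.fromisoformat(str(obj["author_created_at"])[:10])
        return cls(
            tweet_id=str(obj["tweet_id"]),
            created_at=created,
            author_id=str(obj["author_id"]),
            author_followers=int(obj["author_followers"]),
            author_verified=bool(obj["author_verified"]),
            author_created_at=acct_created,
            text=str(obj["text"]),
            urls=tuple(str(u) for u in obj.get("urls", [])),
            source_tweet_id=_opt_str(obj.get("source_tweet_id")),
            source_author_id=_opt_str(obj.get("source_author_id")),
        )


def _opt_str(value) -> str | None:
    return None if value is None else str(value)


def _parse_timestamp(raw: str) -> datetime:
    dt = datetime.fromisoformat(str(raw).replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


@dataclass(frozen=True)
class PeriodWindows:
    """Ordered, labelled, non-overlapping date windows (end date inclusive)."""

    windows: tuple[tuple[str, date, date], ...]

    def __post_init__(self) -> None:
        labels = [w[0] for w in self.windows]
        if len(set(labels)) != len(labels):
            raise ValueError("window labels must be unique")
        prev_end: date | None = None
        for label, start, end in self.windows:
            if end < start:
                raise ValueError(f"window {label!r} ends before it starts")
            if prev_end is not None and start <= prev_end:
                raise ValueError("windows must be chronologically ordered and disjoint")
            prev_end = end

    @classmethod
    def march_2021_study(cls) -> "PeriodWindows":
        """The three week-long windows around the AZ blood-clot news peak."""
        return cls(
            (
                ("Pre-Peak", date(2021, 3, 4), date(2021, 3, 10)),
                ("Peak", date(2021, 3, 11), date(2021, 3, 17)),
                ("Post-Peak", date(2021, 3, 18), date(2021, 3, 25)),
            )
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.windows)

    @property
    def start(self) -> date:
        return self.windows[0][1]

    @property
    def end(self) -> date:
        """Last covered date (inclusive)."""
        return self.windows[-1][2]

    def span(self, label: str) -> tuple[date, date]:
        for lab, start, end in self.windows:
            if lab == label:
                return start, end
        raise KeyError(label)

    def n_days(self, label: str) -> int:
        start, end = self.span(label)
        return (end - start).days + 1

    def assign(self, when: datetime | date) -> str | None:
        """Period label for a timestamp (by UTC calendar date), or None."""
        d = when.date() if isinstance(when, datetime) else when
        for label, start, end in self.windows:
            if start <= d <= end:
                return label
        return None

    def all_dates(self) -> list[date]:
        """Every calendar date from the first window start to the last end."""
        from datetime import timedelta

        out, d = [], self.start
        while d <= self.end:
            out.append(d)
            d += timedelta(days=1)
        return out


@dataclass
class ParsedStream:
    """Records read from one JSON-Lines file plus the malformed-line count."""

    records: list[TweetRecord]
    n_skipped: int = 0

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def read_tweet_stream(path: str | Path) -> ParsedStream:
    """Read a JSON-Lines tweet stream, skipping (and counting) bad lines.

    A line is skipped when it is not valid JSON, is missing a mandatory
    field, or violates a record invariant; skips are logged, never silent.
    An unreadable file raises ``OSError``.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    n_skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                records.append(TweetRecord.from_json_obj(obj))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                n_skipped += 1
                logger.warning("%s:%d skipped malformed line (%s)", path, lineno, exc)
    if n_skipped:
        logger.info("%s: %d malformed line(s) skipped", path, n_skipped)
    return ParsedStream(records=records, n_skipped=n_skipped)


def write_tweet_stream(records: Iterable[TweetRecord], path: str | Path) -> int:
    """Write records as JSON-Lines; returns the number written."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_obj(), ensure_ascii=False) + "\n")
            n += 1
    return n


def load_line_list(path: str | Path) -> list[str]:
    """Read a UTF-8 plain-text list, one entry per line; '#' comments allowed."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out
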
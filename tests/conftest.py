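from __future__ import annotations

from datetime import date, datetime, timezone

import pytest
from hypothesis import HealthCheck, settings

from credflow.records import PeriodWindows, TweetRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    tweet_id: str = "t1",
    when: str = "2021-03-05T12:00:00",
    author: str = "alice",
    followers: int = 10,
    verified: bool = False,
    created: date = date(2015, 1, 1),
    text: str = "covid news",
    urls: tuple[str, ...] = (),
    source: str | None = None,
    source_author: str | None = None,
) -> TweetRecord:
    return TweetRecord(
        tweet_id=tweet_id,
        created_at=datetime.fromisoformat(when).replace(tzinfo=timezone.utc),
        author_id=author,
        author_followers=followers,
        author_verified=verified,
        author_created_at=created,
        text=text,
        urls=urls,
        source_tweet_id=source,
        source_author_id=source_author,
    )


@pytest.fixture(scope="session")
def windows() -> PeriodWindows:
    return PeriodWindows.march_2021_study()


@pytest.fixture(scope="session")
def default_stream():
    """One default-configuration synthetic stream, shared across tests."""
    from credflow.simulate import SimConfig, generate_stream, generate_users

    config = SimConfig(seed=7)
    users = generate_users(config)
    records, truth = generate_stream(users, config)
    return config, users, records, truth
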
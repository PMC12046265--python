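from datetime import datetime, timedelta, timezone

import pytest

from cardiotriage.core_model import (
    EventProfile,
    HeartCheck,
    SymptomEpisode,
    Vocabulary,
)

#: fixed evaluation clock used across the suite
NOW = datetime(2021, 3, 1, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary.default()


@pytest.fixture
def profile() -> EventProfile:
    return EventProfile(
        user_id="u1",
        qualities=frozenset({"heavy", "tight"}),
        locations=frozenset({"chest_center"}),
        radiation=frozenset({"arm_left"}),
        associated=frozenset({"shortness_of_breath"}),
        recorded_at=NOW - timedelta(days=30),
    )


def make_episode(
    hours_ago: float = 1.0,
    qualities=(),
    locations=(),
    radiation=(),
    associated=(),
) -> SymptomEpisode:
    return SymptomEpisode(
        qualities=frozenset(qualities),
        locations=frozenset(locations),
        radiation=frozenset(radiation),
        associated=frozenset(associated),
        onset_at=NOW - timedelta(hours=hours_ago),
    )


def make_check(episodes, user_id="u1", asked_at=NOW) -> HeartCheck:
    return HeartCheck(
        user_id=user_id,
        episodes=tuple(sorted(episodes, key=lambda e: e.onset_at)),
        asked_at=asked_at,
    )
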
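from datetime import datetime, timedelta, timezone

import pytest

from chatmine.corpus import Corpus, Message, UserRecord

T0 = datetime(2018, 3, 5, 9, 0, tzinfo=timezone.utc)  # a Monday


def msg(
    i,
    user="u1",
    direction="inbound",
    hours=0.0,
    body=None,
    language=None,
    agent=None,
):
    return Message(
        message_id=f"m{i}",
        user_id=user,
        direction=direction,
        timestamp=T0 + timedelta(hours=hours),
        body=body,
        language=language,
        agent_id=agent,
    )


def user(uid, sex="unknown", age=None, pref="unknown"):
    return UserRecord(user_id=uid, sex=sex, age_years=age, language_preference=pref)


@pytest.fixture
def make_corpus():
    def _make(messages, users=()):
        return Corpus(messages=list(messages), users={u.user_id: u for u in users})

    return _make
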
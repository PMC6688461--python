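"""Conversation segmentation, coded-conversation statistics, topic pairs."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from chatmine.conversations import (
    conversation_stats,
    conversations_frame,
    question_distribution,
    sample_high_engagement,
    segment_conversations,
    topic_cooccurrence,
)
from chatmine.errors import EmptyInputError

from conftest import msg, user


class TestSegmentation:
    def test_gap_over_threshold_splits(self):
        msgs = [msg(1, hours=0), msg(2, hours=1), msg(3, hours=30)]
        convs = segment_conversations(msgs, timedelta(hours=24))
        assert [len(c.message_ids) for c in convs] == [2, 1]

    def test_single_message_single_conversation(self):
        convs = segment_conversations([msg(1)])
        assert len(convs) == 1
        assert convs[0].n_user_messages == 1

    def test_infinite_threshold_one_conversation(self):
        msgs = [msg(i, hours=i * 100) for i in range(5)]
        convs = segment_conversations(msgs, timedelta(days=10_000))
        assert len(convs) == 1

    def test_partition_conserves_messages(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            times = np.cumsum(rng.exponential(20, size=rng.integers(1, 20)))
            msgs = [msg(i, hours=float(t)) for i, t in enumerate(times)]
            convs = segment_conversations(msgs, timedelta(hours=24))
            ids = [mid for c in convs for mid in c.message_ids]
            assert sorted(ids) == sorted(m.message_id for m in msgs)

    def test_shrinking_threshold_never_merges(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            times = np.cumsum(rng.exponential(20, size=rng.integers(1, 15)))
            msgs = [msg(i, hours=float(t)) for i, t in enumerate(times)]
            wide = len(segment_conversations(msgs, timedelta(hours=36)))
            narrow = len(segment_conversations(msgs, timedelta(hours=12)))
            assert narrow >= wide

    def test_user_and_agent_counts(self):
        msgs = [msg(1, hours=0), msg(2, hours=0.1, direction="outbound", agent="a1")]
        conv = segment_conversations(msgs)[0]
        assert (conv.n_user_messages, conv.n_agent_messages) == (1, 1)


class TestConversationStats:
    def test_messages_per_conversation_hand_mean(self):
        conversations = pd.DataFrame(
            {
                "conversation_id": ["c1", "c2", "c3"],
                "user_id": ["u1", "u1", "u2"],
                "n_messages": [10, 10, 16],
            }
        )
        topics = pd.DataFrame({"conversation_id": [], "topic": []})
        users = {"u1": user("u1"), "u2": user("u2")}
        out = conversation_stats(conversations, topics, users)
        all_row = out[out["group"] == "All"].iloc[0]
        assert all_row["messages_per_convo_mean"] == pytest.approx(12.0)
        assert all_row["n_conversations"] == 3
        assert all_row["n_users"] == 2

    def test_topics_per_conversation(self):
        conversations = pd.DataFrame(
            {"conversation_id": ["c1"], "user_id": ["u1"], "n_messages": [4]}
        )
        topics = pd.DataFrame(
            {"conversation_id": ["c1", "c1"], "topic": ["contraception", "sti"]}
        )
        out = conversation_stats(conversations, topics, {"u1": user("u1")})
        assert out[out["group"] == "All"].iloc[0]["topics_per_convo_mean"] == 2.0

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            conversation_stats(
                pd.DataFrame(columns=["conversation_id", "user_id", "n_messages"]),
                pd.DataFrame(columns=["conversation_id", "topic"]),
                {},
            )


class TestQuestionDistribution:
    def coded(self, cats, code="question_request", myth=None):
        n = len(cats)
        return pd.DataFrame(
            {
                "conversation_id": ["c1"] * n,
                "user_id": ["u1"] * n,
                "code": [code] * n,
                "category": cats,
                "myth": myth if myth is not None else [False] * n,
            }
        )

    def test_hand_tally_shares(self):
        dist = question_distribution(self.coded([1] * 5 + [3] * 3 + [5] * 2))
        assert dist.pct_by_category == {1: 50.0, 2: 0.0, 3: 30.0, 4: 0.0, 5: 20.0, 6: 0.0}

    def test_all_one_category(self):
        dist = question_distribution(self.coded([2] * 4))
        assert dist.pct_by_category[2] == 100.0
        assert sum(dist.pct_by_category.values()) == 100.0

    def test_myth_share_among_information_requests(self):
        # 516 information requests, 24 flagged as myths -> 4.651%
        cats = [1] * 516 + [3] * 100
        myth = [True] * 24 + [False] * (516 - 24) + [False] * 100
        dist = question_distribution(self.coded(cats, myth=myth))
        assert dist.n_information_requests == 516
        assert dist.pct_myth_among_information == pytest.approx(100 * 24 / 516)
        assert dist.pct_myth_among_information == pytest.approx(4.651, abs=5e-3)

    def test_non_questions_excluded(self):
        df = pd.concat(
            [self.coded([1, 2]), self.coded([None, None], code="greeting")],
            ignore_index=True,
        )
        assert question_distribution(df).n_questions == 2

    def test_no_questions_raises(self):
        with pytest.raises(EmptyInputError):
            question_distribution(self.coded([None], code="response"))


class TestTopicCooccurrence:
    def topics(self, mapping):
        rows = [(cid, t) for cid, ts in mapping.items() for t in ts]
        return pd.DataFrame(rows, columns=["conversation_id", "topic"])

    def test_two_topic_conversation_counts_one_pair(self):
        out = topic_cooccurrence(self.topics({"c1": ["contraception", "fertility"]}))
        assert len(out) == 1 and out.loc[0, "n"] == 1

    def test_three_topics_three_pairs(self):
        out = topic_cooccurrence(self.topics({"c1": ["a", "b", "c"]}))
        assert len(out) == 3 and out["n"].sum() == 3

    def test_single_topic_conversations_excluded(self):
        out = topic_cooccurrence(self.topics({"c1": ["a"], "c2": ["b"]}))
        assert out.empty

    def test_total_matches_binomial_sum(self):
        rng = np.random.default_rng(0)
        mapping = {
            f"c{i}": [f"t{j}" for j in rng.choice(10, rng.integers(1, 6), replace=False)]
            for i in range(50)
        }
        out = topic_cooccurrence(self.topics(mapping))
        expected = sum(
            len(ts) * (len(ts) - 1) // 2 for ts in mapping.values() if len(ts) >= 2
        )
        assert out["n"].sum() == expected


class TestHighEngagementSampler:
    def test_requires_weekly_threshold_and_balances_sex(self, make_corpus):
        messages, users = [], []
        i = 0
        for j in range(6):
            uid = f"u{j}"
            users.append(user(uid, sex="female" if j % 2 else "male"))
            n = 8 if j < 4 else 2  # only first four reach 7 messages in a week
            for _ in range(n):
                i += 1
                messages.append(msg(i, uid, hours=i * 0.1, language="en"))
        corpus = make_corpus(messages, users)
        picked = sample_high_engagement(corpus, per_sex=2, seed=1)
        assert set(picked) == {"u0", "u1", "u2", "u3"}

    def test_deterministic_given_seed(self, make_corpus):
        messages, users = [], []
        i = 0
        for j in range(30):
            uid = f"u{j}"
            users.append(user(uid, sex="female"))
            for _ in range(8):
                i += 1
                messages.append(msg(i, uid, hours=i * 0.01, language="en"))
        corpus = make_corpus(messages, users)
        a = sample_high_engagement(corpus, per_sex=5, seed=7)
        b = sample_high_engagement(corpus, per_sex=5, seed=7)
        assert a == b and len(a) == 5
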
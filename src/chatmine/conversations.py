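"""Conversation segmentation and coded-conversation analytics.

A conversation is a maximal run of one user's messages (both directions)
with no gap longer than a threshold (default 24 h) between consecutive
messages — a reproducible proxy for manual conversation delimitation.
Topic labels, message-level codes and question categories are *input data*
produced by human coders; this module defines their schema and the
aggregations over them.

Question categories (per coded question/request message):

    1  factual information about causes
    2  factual information about the meaning of concepts/terms
    3  requests for advice
    4  access to services and products
    5  reporting symptoms / requesting diagnosis
    6  other

Categories 1–2 together are the "information requests"; the myth flag
(whether a question asks about a common myth) is defined on those.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, Message, UserRecord
from .errors import EmptyInputError, ParameterError
from .frequency import DEFAULT_AGE_BANDS, age_band_label

MESSAGE_CODES = ("question_request", "response", "greeting", "other")
QUESTION_CATEGORIES = (1, 2, 3, 4, 5, 6)
INFORMATION_CATEGORIES = (1, 2)


@dataclass
class Conversation:
    conversation_id: str
    user_id: str
    message_ids: list[str]
    n_user_messages: int
    n_agent_messages: int
    start: datetime
    end: datetime


def segment_conversations(
    user_stream: Sequence[Message],
    gap_threshold: timedelta = timedelta(hours=24),
    user_id: str | None = None,
) -> list[Conversation]:
    """Split one user's time-ordered messages at long inactivity gaps.

    A new conversation starts whenever the gap between consecutive messages
    exceeds ``gap_threshold``; every message lands in exactly one
    conversation, so segmentation is a partition of the stream.
    """
    msgs = sorted(user_stream, key=lambda m: (m.timestamp, m.message_id))
    if not msgs:
        return []
    uid = user_id or msgs[0].user_id
    groups: list[list[Message]] = [[msgs[0]]]
    for prev, cur in zip(msgs, msgs[1:]):
        if cur.timestamp - prev.timestamp > gap_threshold:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    out = []
    for k, grp in enumerate(groups, start=1):
        n_user = sum(1 for m in grp if m.direction == "inbound")
        out.append(
            Conversation(
                conversation_id=f"{uid}-c{k}",
                user_id=uid,
                message_ids=[m.message_id for m in grp],
                n_user_messages=n_user,
                n_agent_messages=len(grp) - n_user,
                start=grp[0].timestamp,
                end=grp[-1].timestamp,
            )
        )
    return out


def segment_corpus(
    corpus: Corpus, gap_threshold: timedelta = timedelta(hours=24)
) -> list[Conversation]:
    """Segment every user's stream; conversations ordered by user then time."""
    out: list[Conversation] = []
    for uid in sorted(corpus.by_user()):
        out.extend(segment_conversations(corpus.by_user()[uid], gap_threshold, uid))
    return out


def conversations_frame(conversations: Iterable[Conversation]) -> pd.DataFrame:
    rows = [
        (
            c.conversation_id,
            c.user_id,
            c.n_user_messages,
            c.n_agent_messages,
            c.n_user_messages + c.n_agent_messages,
        )
        for c in conversations
    ]
    return pd.DataFrame(
        rows,
        columns=["conversation_id", "user_id", "n_user_messages", "n_agent_messages", "n_messages"],
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return (float("nan"), float("nan"))
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return (float(arr.mean()), float(sd))


def conversation_stats(
    conversations: pd.DataFrame,
    topics: pd.DataFrame,
    users: Mapping[str, UserRecord],
    age_bands: Sequence[tuple[int, int | None]] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Per-group conversation characteristics table.

    ``conversations`` needs columns conversation_id, user_id, n_messages;
    ``topics`` has one row per (conversation_id, topic).  Output rows: All,
    each sex, and sex×age-band groups, with columns n_users, n_messages,
    n_conversations, convos_per_person mean/sd, messages_per_convo mean/sd,
    topics_per_convo mean/sd.
    """
    if conversations.empty:
        raise EmptyInputError("no conversations")
    topics_per_convo = topics.groupby("conversation_id").size() if len(topics) else pd.Series(dtype=int)

    def group_row(label: str, uids: set[str]) -> tuple:
        convs = conversations[conversations["user_id"].isin(uids)]
        per_person = convs.groupby("user_id").size()
        cp_mean, cp_sd = _mean_sd(per_person.values)
        mc_mean, mc_sd = _mean_sd(convs["n_messages"].values)
        tp = topics_per_convo.reindex(convs["conversation_id"]).dropna()
        tp_mean, tp_sd = _mean_sd(tp.values)
        return (
            label,
            len(uids & set(conversations["user_id"])),
            int(convs["n_messages"].sum()),
            len(convs),
            cp_mean,
            cp_sd,
            mc_mean,
            mc_sd,
            tp_mean,
            tp_sd,
        )

    all_uids = set(conversations["user_id"])
    rows = [group_row("All", all_uids)]
    for sex in ("male", "female"):
        sex_uids = {u for u in all_uids if users.get(u) and users[u].sex == sex}
        label = "Men" if sex == "male" else "Women"
        rows.append(group_row(label, sex_uids))
        for lo, hi in age_bands:
            band = f"{lo}+" if hi is None else f"{lo}-{hi}"
            band_uids = {
                u
                for u in sex_uids
                if users[u].age_years is not None
                and age_band_label(users[u].age_years, age_bands) == band
            }
            if band_uids:
                rows.append(group_row(f"{label}, {band}", band_uids))
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_users",
            "n_messages",
            "n_conversations",
            "convos_per_person_mean",
            "convos_per_person_sd",
            "messages_per_convo_mean",
            "messages_per_convo_sd",
            "topics_per_convo_mean",
            "topics_per_convo_sd",
        ],
    )


@dataclass
class QuestionDistribution:
    """Shares over the six question categories plus the myth share."""

    pct_by_category: dict[int, float]
    n_questions: int
    pct_myth_among_information: float | None
    n_information_requests: int


def question_distribution(coded_messages: pd.DataFrame) -> QuestionDistribution:
    """Distribution of coded user questions/requests.

    ``coded_messages`` needs columns code, category (nullable), myth
    (boolean, meaningful on information requests).  Category shares are over
    messages coded ``question_request`` and sum to 100; the myth share's
    denominator is the information requests (categories 1–2).
    """
    questions = coded_messages[coded_messages["code"] == "question_request"]
    if questions.empty:
        raise EmptyInputError("no coded questions")
    bad = set(questions["category"].dropna().astype(int)) - set(QUESTION_CATEGORIES)
    if bad:
        raise ParameterError(f"unknown question categories {sorted(bad)}")
    n = len(questions)
    cat_counts = Counter(questions["category"].astype(int))
    info = questions[questions["category"].astype(int).isin(INFORMATION_CATEGORIES)]
    n_info = len(info)
    myth_pct = 100.0 * info["myth"].fillna(False).astype(bool).mean() if n_info else None
    return QuestionDistribution(
        pct_by_category={c: 100.0 * cat_counts.get(c, 0) / n for c in QUESTION_CATEGORIES},
        n_questions=n,
        pct_myth_among_information=myth_pct,
        n_information_requests=n_info,
    )


def topic_cooccurrence(topics: pd.DataFrame) -> pd.DataFrame:
    """Unordered topic-pair counts over multi-topic conversations.

    Each conversation with k >= 2 topics contributes each of its C(k, 2)
    pairs once; single-topic conversations are excluded.  Output columns:
    topic_a, topic_b, n (topic_a < topic_b).
    """
    ctr: Counter = Counter()
    for _, grp in topics.groupby("conversation_id"):
        labels = sorted(set(grp["topic"]))
        if len(labels) < 2:
            continue
        ctr.update(itertools.combinations(labels, 2))
    rows = sorted(ctr.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(
        [(a, b, n) for (a, b), n in rows], columns=["topic_a", "topic_b", "n"]
    )


def sample_high_engagement(
    corpus: Corpus,
    per_sex: int = 50,
    min_weekly_messages: int = 7,
    language: str | None = "en",
    seed: int = 0,
) -> list[str]:
    """Seeded sample of high-engagement users, balanced by sex.

    Eligible users sent at least ``min_weekly_messages`` inbound messages
    (optionally of one language) within a single ISO week.  Up to
    ``per_sex`` users are drawn per sex without replacement; if fewer are
    eligible, all are taken.
    """
    weekly: dict[tuple[str, int, int], int] = {}
    for m in corpus.inbound():
        if language is not None and m.language != language:
            continue
        key = (m.user_id, *m.iso_week())
        weekly[key] = weekly.get(key, 0) + 1
    eligible = sorted({uid for (uid, _, _), n in weekly.items() if n >= min_weekly_messages})
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for sex in ("female", "male"):
        pool = [u for u in eligible if corpus.users[u].sex == sex]
        take = min(per_sex, len(pool))
        out.extend(sorted(rng.choice(pool, size=take, replace=False))) if take else None
    return out
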
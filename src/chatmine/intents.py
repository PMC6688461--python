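"""Intent-label adjudication by double agreement, and intent distributions.

Each user question is presented to human raters one at a time; the final
intent label is the first label given by two *distinct* raters, resolved at
the earliest presentation index where such a pair exists.  Questions whose
event sequence never produces agreement stay unresolved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import UserRecord
from .errors import EmptyInputError, IntegrityError


@dataclass(frozen=True)
class LabelEvent:
    question_id: str
    rater_id: str
    intent_label: str
    sequence_index: int


@dataclass
class IntentResolution:
    question_id: str
    final_label: str | None
    n_presentations: int
    agreeing_raters: tuple[str, str] | None

    @property
    def resolved(self) -> bool:
        return self.final_label is not None


def resolve_double_agreement(events: Sequence[LabelEvent]) -> IntentResolution:
    """Resolve one question's ordered label events.

    ``n_presentations`` is the sequence index at which agreement first
    occurred (or the total number of presentations if unresolved).  The same
    rater repeating a label does not count as agreement.
    """
    ordered = sorted(events, key=lambda e: e.sequence_index)
    if not ordered:
        raise EmptyInputError("no label events for question")
    qid = ordered[0].question_id
    seen_idx: set[int] = set()
    raters_by_label: dict[str, list[str]] = {}
    for event in ordered:
        if event.question_id != qid:
            raise IntegrityError("events span multiple questions")
        if event.sequence_index in seen_idx:
            raise IntegrityError(
                f"duplicate sequence_index {event.sequence_index} for question {qid}"
            )
        seen_idx.add(event.sequence_index)
        raters = raters_by_label.setdefault(event.intent_label, [])
        prior_distinct = [r for r in raters if r != event.rater_id]
        if prior_distinct:
            return IntentResolution(
                question_id=qid,
                final_label=event.intent_label,
                n_presentations=event.sequence_index,
                agreeing_raters=(prior_distinct[0], event.rater_id),
            )
        raters.append(event.rater_id)
    return IntentResolution(
        question_id=qid,
        final_label=None,
        n_presentations=ordered[-1].sequence_index,
        agreeing_raters=None,
    )


def resolve_all(events: Iterable[LabelEvent]) -> pd.DataFrame:
    """Resolve every question; one row per question_id."""
    by_q: dict[str, list[LabelEvent]] = {}
    for e in events:
        by_q.setdefault(e.question_id, []).append(e)
    rows = []
    for qid in sorted(by_q):
        res = resolve_double_agreement(by_q[qid])
        rows.append((qid, res.final_label, res.n_presentations, res.resolved))
    return pd.DataFrame(
        rows, columns=["question_id", "final_label", "n_presentations", "resolved"]
    )


@dataclass
class IntentDistribution:
    """Percent shares of resolved intents on several margins."""

    overall: pd.DataFrame  # intent, n, pct
    by_sex: pd.DataFrame  # intent, sex, n, pct (pct within sex)
    by_marketed: pd.DataFrame  # intent, marketed, n, pct
    n_resolved: int
    n_unresolved: int


def _share_frame(counts: Counter, total_by_group: Mapping | None = None) -> pd.DataFrame:
    rows = []
    if total_by_group is None:
        total = sum(counts.values())
        for intent in sorted(counts):
            rows.append((intent, counts[intent], 100.0 * counts[intent] / total))
        return pd.DataFrame(rows, columns=["intent", "n", "pct"])
    for (intent, group) in sorted(counts):
        n = counts[(intent, group)]
        rows.append((intent, group, n, 100.0 * n / total_by_group[group]))
    return pd.DataFrame(rows, columns=["intent", "group", "n", "pct"])


def intent_distribution(
    resolutions: pd.DataFrame,
    question_users: Mapping[str, str],
    users: Mapping[str, UserRecord],
    marketed_flags: Mapping[str, bool] | None = None,
) -> IntentDistribution:
    """Intent shares overall, by sender sex, and by marketing status.

    ``question_users`` maps question_id to user_id; ``marketed_flags`` marks
    intents that were the subject of marketing campaigns (input data, not
    inferred).  Shares are over resolved questions and sum to 100 on each
    margin; unresolved questions are excluded and counted.
    """
    resolved = resolutions[resolutions["resolved"]]
    if resolved.empty:
        raise EmptyInputError("no resolved questions")
    n_unresolved = int((~resolutions["resolved"]).sum())

    overall = _share_frame(Counter(resolved["final_label"]))

    sex_counts: Counter = Counter()
    sex_totals: Counter = Counter()
    for _, row in resolved.iterrows():
        uid = question_users.get(row["question_id"])
        user = users.get(uid) if uid is not None else None
        sex = user.sex if user is not None else "unknown"
        sex_counts[(row["final_label"], sex)] += 1
        sex_totals[sex] += 1
    by_sex = _share_frame(sex_counts, sex_totals).rename(columns={"group": "sex"})

    flags = marketed_flags or {}
    mkt_counts: Counter = Counter()
    mkt_totals: Counter = Counter()
    for label, n in Counter(resolved["final_label"]).items():
        group = "marketed" if flags.get(label, False) else "not_marketed"
        mkt_counts[(label, group)] += n
    for (_, group), n in mkt_counts.items():
        mkt_totals[group] += n
    by_marketed = _share_frame(mkt_counts, mkt_totals).rename(
        columns={"group": "marketed"}
    )

    return IntentDistribution(
        overall=overall,
        by_sex=by_sex,
        by_marketed=by_marketed,
        n_resolved=len(resolved),
        n_unresolved=n_unresolved,
    )


def events_frame(events: Iterable[LabelEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.question_id, e.rater_id, e.intent_label, e.sequence_index) for e in events],
        columns=["question_id", "rater_id", "label", "sequence_index"],
    )


def events_from_frame(df: pd.DataFrame) -> list[LabelEvent]:
    """Read label events from a (question_id, rater_id, label, sequence_index) table."""
    return [
        LabelEvent(
            question_id=str(r.question_id),
            rater_id=str(r.rater_id),
            intent_label=str(r.label),
            sequence_index=int(r.sequence_index),
        )
        for r in df.itertuples()
    ]
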
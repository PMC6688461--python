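"""Per-user engagement patterns and weekly message volume.

Every user with at least one inbound message falls in exactly one of five
patterns, a pure function of (inbound count, outbound count):

    (1, 1)   single_in_single_out      (1, >1)  single_in_multi_out
    (>1, 1)  multi_in_single_out       (>1, >1) multi_in_multi_out
    (>=1, 0) no_reply

The partition is exhaustive by construction, so pattern shares always sum to
100%; views that report only the three dominant classes are a presentation
choice, not a different classification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping

import pandas as pd

from .corpus import Corpus, UserRecord
from .errors import EmptyInputError

PATTERNS = (
    "single_in_single_out",
    "multi_in_single_out",
    "multi_in_multi_out",
    "single_in_multi_out",
    "no_reply",
)


def classify_pattern(n_inbound: int, n_outbound: int) -> str:
    if n_inbound < 1:
        raise ValueError("engagement patterns require >= 1 inbound message")
    if n_outbound == 0:
        return "no_reply"
    if n_inbound == 1:
        return "single_in_single_out" if n_outbound == 1 else "single_in_multi_out"
    return "multi_in_single_out" if n_outbound == 1 else "multi_in_multi_out"


def classify_engagement(corpus: Corpus) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every inbound-active user; returns (records, percent shares).

    Outbound messages are attributed to users by the user_id on the reply.
    """
    n_in: Counter = Counter()
    n_out: Counter = Counter()
    for m in corpus.messages:
        (n_in if m.direction == "inbound" else n_out)[m.user_id] += 1
    rows = [
        (uid, n_in[uid], n_out.get(uid, 0), classify_pattern(n_in[uid], n_out.get(uid, 0)))
        for uid in sorted(n_in)
    ]
    records = pd.DataFrame(rows, columns=["user_id", "n_inbound", "n_outbound", "pattern"])
    if len(records):
        shares = {
            p: 100.0 * (records["pattern"] == p).mean() for p in PATTERNS
        }
    else:
        shares = {p: 0.0 for p in PATTERNS}
    return records, shares


def single_message_rate_ratio(
    records: pd.DataFrame, users: Mapping[str, UserRecord]
) -> float | None:
    """Male-to-female ratio of the single_in_single_out share.

    Conditions on users with known sex; returns None (undefined) when the
    female share is zero; raises when no user has a known sex.
    """
    sex = records["user_id"].map(
        lambda uid: users[uid].sex if uid in users else "unknown"
    )
    known = records[sex.isin(("female", "male"))].assign(sex=sex[sex.isin(("female", "male"))])
    if known.empty:
        raise EmptyInputError("no users with known sex")
    shares = {}
    for s in ("female", "male"):
        grp = known[known["sex"] == s]
        shares[s] = (grp["pattern"] == "single_in_single_out").mean() if len(grp) else None
    if not shares["female"] or shares["male"] is None:
        return None
    return shares["male"] / shares["female"]


@dataclass
class WeeklyVolume:
    """Inbound/outbound counts per ISO week, zero-filled over the span."""

    table: pd.DataFrame  # columns iso_year, iso_week, n_inbound, n_outbound


def _week_start(iso_year: int, iso_week: int) -> date:
    return date.fromisocalendar(iso_year, iso_week, 1)


def weekly_volume(corpus: Corpus) -> WeeklyVolume:
    """Message counts per ISO-8601 week, contiguous over the corpus span."""
    if not corpus.messages:
        raise EmptyInputError("corpus has no messages")
    counts: dict[tuple[int, int], list[int]] = {}
    for m in corpus.messages:
        key = m.iso_week()
        cell = counts.setdefault(key, [0, 0])
        cell[0 if m.direction == "inbound" else 1] += 1

    first = min(_week_start(*k) for k in counts)
    last = max(_week_start(*k) for k in counts)
    rows = []
    cursor = first
    while cursor <= last:
        iso = cursor.isocalendar()
        cell = counts.get((iso[0], iso[1]), [0, 0])
        rows.append((iso[0], iso[1], cell[0], cell[1]))
        cursor += timedelta(weeks=1)
    return WeeklyVolume(
        pd.DataFrame(rows, columns=["iso_year", "iso_week", "n_inbound", "n_outbound"])
    )
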
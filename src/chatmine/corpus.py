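"""Core data model for two-way chat corpora.

A corpus is a collection of :class:`Message` objects (inbound user messages and
outbound agent replies) plus a table of :class:`UserRecord` demographics.
Readers and writers support flat CSV and JSON-lines layouts, a load report
records rejected rows, and :func:`export_term_counts` applies the
privacy-preserving minimum-count filter used when sharing token tables.
"""

from __future__ import annotations

import csv
import json
import statistics
from collections import Counter
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyInputError, IntegrityError, ParameterError, SchemaError

DIRECTIONS = ("inbound", "outbound")
LANGUAGES = ("en", "sw", "und")
SEXES = ("female", "male", "unknown")

#: Columns of a message file, in canonical order.
MESSAGE_COLUMNS = (
    "message_id",
    "user_id",
    "direction",
    "timestamp",
    "body",
    "language",
    "agent_id",
)
USER_COLUMNS = ("user_id", "sex", "age", "language_preference")

#: Header mapping for the archived message meta-data dialect (week-stamped,
#: no raw text).  Keys are canonical names, values the archive's headers.
ARCHIVE_METADATA_MAP = {
    "message_id": "id",
    "user_id": "user",
    "direction": "direction",
    "timestamp": "time",
}


@dataclass
class Message:
    """One chat message.

    ``direction`` is ``inbound`` (user → service) or ``outbound`` (agent →
    user).  ``language`` is one of ``en``/``sw``/``und`` once detection has
    run, or ``None`` beforehand.  ``agent_id`` is only meaningful on outbound
    messages.  ``body`` may be ``None`` in anonymized exports.
    """

    message_id: str
    user_id: str
    direction: str
    timestamp: datetime
    body: str | None = None
    language: str | None = None
    agent_id: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise IntegrityError(f"invalid direction {self.direction!r}")
        if self.timestamp.tzinfo is None:
            raise IntegrityError(f"naive timestamp on message {self.message_id}")
        if self.direction == "inbound" and self.agent_id is not None:
            raise IntegrityError(
                f"inbound message {self.message_id} carries agent_id"
            )
        if self.language is not None and self.language not in LANGUAGES:
            raise IntegrityError(f"invalid language {self.language!r}")

    def iso_week(self) -> tuple[int, int]:
        """ISO-8601 (year, week) of the message timestamp."""
        iso = self.timestamp.isocalendar()
        return (iso[0], iso[1])


@dataclass
class UserRecord:
    """Demographics and stated language preference for one user."""

    user_id: str
    sex: str = "unknown"
    age_years: float | None = None
    language_preference: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise IntegrityError(f"invalid sex {self.sex!r}")
        if self.age_years is not None and not (10 <= self.age_years <= 100):
            raise IntegrityError(
                f"age {self.age_years} outside [10, 100] for user {self.user_id}"
            )
        if self.language_preference not in ("en", "sw", "unknown"):
            raise IntegrityError(
                f"invalid language_preference {self.language_preference!r}"
            )


def placeholder_user(user_id: str) -> UserRecord:
    """Record for a user seen in messages but absent from the user table."""
    return UserRecord(user_id=user_id)


@dataclass
class Corpus:
    """Messages plus user records; unresolved users get placeholders."""

    messages: list[Message]
    users: dict[str, UserRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.messages:
            if m.message_id in seen:
                raise IntegrityError(f"duplicate message_id {m.message_id!r}")
            seen.add(m.message_id)
            if m.user_id not in self.users:
                self.users[m.user_id] = placeholder_user(m.user_id)

    def inbound(self) -> list[Message]:
        return [m for m in self.messages if m.direction == "inbound"]

    def outbound(self) -> list[Message]:
        return [m for m in self.messages if m.direction == "outbound"]

    def by_user(self, direction: str | None = None) -> dict[str, list[Message]]:
        """Messages grouped by user, optionally filtered by direction."""
        out: dict[str, list[Message]] = {}
        for m in self.messages:
            if direction is not None and m.direction != direction:
                continue
            out.setdefault(m.user_id, []).append(m)
        return out


@dataclass
class LoadReport:
    """Row-level accounting from a corpus read."""

    n_read: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] += 1


@dataclass
class CorpusSummary:
    """Headline descriptives of a corpus.

    Per-user statistics are over inbound messages only, and only users with at
    least one inbound message enter the per-user denominators.  Percentages are
    over users with the attribute known; ``n_*_known`` give the denominators.
    """

    n_users: int
    n_inbound: int
    n_outbound: int
    n_total: int
    inbound_per_user_mean: float
    inbound_per_user_median: float
    inbound_per_user_sd: float
    pct_female: float | None
    n_sex_known: int
    pct_prefers_english: float | None
    n_pref_known: int
    age_mean: float | None
    age_sd: float | None
    n_age_known: int


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw)
    if ts.tzinfo is None:
        raise ValueError("naive timestamp")
    return ts


def _row_to_message(row: Mapping[str, object]) -> Message:
    def opt(key: str) -> str | None:
        v = row.get(key)
        if v is None:
            return None
        v = str(v)
        return v if v != "" else None

    direction = opt("direction")
    if direction is None:
        raise ValueError("missing direction")
    ts_raw = opt("timestamp")
    if ts_raw is None:
        raise ValueError("missing timestamp")
    return Message(
        message_id=str(row["message_id"]),
        user_id=str(row["user_id"]),
        direction=direction,
        timestamp=_parse_timestamp(ts_raw),
        body=opt("body"),
        language=opt("language"),
        agent_id=opt("agent_id"),
    )


def _iter_rows(path: Path, format: str) -> tuple[list[str], Iterable[dict]]:
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            rows = list(reader)
        return header, rows
    if format == "jsonl":
        rows = []
        keys: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                keys.update(obj)
                rows.append(obj)
        return sorted(keys), rows
    raise ParameterError(f"unknown format {format!r}")


def read_corpus(
    messages_path: str | Path,
    users_path: str | Path | None = None,
    format: str = "csv",
    header_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[Corpus, LoadReport]:
    """Read a corpus from a message file and optional user table.

    ``header_map`` renames canonical column names to the file's headers (e.g.
    :data:`ARCHIVE_METADATA_MAP` for the archived meta-data dialect).  Rows
    with unparseable timestamps or a missing direction are rejected and
    counted in the returned :class:`LoadReport`; with ``strict=True`` the
    first bad row raises instead.
    """
    messages_path = Path(messages_path)
    header, rows = _iter_rows(messages_path, format)
    mapping = dict(header_map or {})
    required = ("message_id", "user_id", "direction", "timestamp")
    for canon in required:
        col = mapping.get(canon, canon)
        if col not in header:
            raise SchemaError(f"message file missing required column {col!r}")

    report = LoadReport()
    messages: list[Message] = []
    seen_ids: set[str] = set()
    for raw in rows:
        report.n_read += 1
        row = {canon: raw.get(mapping.get(canon, canon)) for canon in MESSAGE_COLUMNS}
        try:
            msg = _row_to_message(row)
        except (ValueError, IntegrityError, KeyError) as exc:
            if strict:
                raise IntegrityError(f"bad row: {exc}") from exc
            report.reject(str(exc) or type(exc).__name__)
            continue
        if msg.message_id in seen_ids:
            raise IntegrityError(f"duplicate message_id {msg.message_id!r}")
        seen_ids.add(msg.message_id)
        messages.append(msg)

    users: dict[str, UserRecord] = {}
    if users_path is not None:
        users = read_users(users_path)
    corpus = Corpus(messages=messages, users=users)
    return corpus, report


def read_users(path: str | Path) -> dict[str, UserRecord]:
    """Read a user attribute CSV (user_id, sex, age, language_preference)."""
    path = Path(path)
    users: dict[str, UserRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "user_id" not in reader.fieldnames:
            raise SchemaError("user file missing required column 'user_id'")
        for row in reader:
            uid = row["user_id"]
            if uid in users:
                raise IntegrityError(f"duplicate user_id {uid!r}")
            age_raw = (row.get("age") or "").strip()
            age = float(age_raw) if age_raw else None
            users[uid] = UserRecord(
                user_id=uid,
                sex=(row.get("sex") or "unknown") or "unknown",
                age_years=age,
                language_preference=(row.get("language_preference") or "unknown")
                or "unknown",
            )
    return users


def write_corpus(
    corpus: Corpus,
    messages_path: str | Path,
    users_path: str | Path | None = None,
    format: str = "csv",
) -> None:
    """Write a corpus back out; inverse of :func:`read_corpus`."""
    messages_path = Path(messages_path)
    rows = []
    for m in corpus.messages:
        rows.append(
            {
                "message_id": m.message_id,
                "user_id": m.user_id,
                "direction": m.direction,
                "timestamp": m.timestamp.isoformat(),
                "body": m.body,
                "language": m.language,
                "agent_id": m.agent_id,
            }
        )
    if format == "csv":
        with open(messages_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=MESSAGE_COLUMNS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    elif format == "jsonl":
        with open(messages_path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise ParameterError(f"unknown format {format!r}")

    if users_path is not None:
        with open(users_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=USER_COLUMNS)
            writer.writeheader()
            for u in corpus.users.values():
                writer.writerow(
                    {
                        "user_id": u.user_id,
                        "sex": u.sex,
                        "age": "" if u.age_years is None else u.age_years,
                        "language_preference": u.language_preference,
                    }
                )


def summarize_corpus(corpus: Corpus) -> CorpusSummary:
    """Compute headline corpus descriptives.

    Raises :class:`EmptyInputError` on an empty corpus.
    """
    if not corpus.messages:
        raise EmptyInputError("corpus has no messages")
    n_in = sum(1 for m in corpus.messages if m.direction == "inbound")
    n_out = len(corpus.messages) - n_in

    per_user = Counter(m.user_id for m in corpus.messages if m.direction == "inbound")
    counts = sorted(per_user.values())
    if counts:
        mean = statistics.fmean(counts)
        median = float(statistics.median(counts))
        sd = statistics.stdev(counts) if len(counts) > 1 else 0.0
    else:
        mean = median = sd = float("nan")

    sexes = [u.sex for u in corpus.users.values() if u.sex != "unknown"]
    prefs = [
        u.language_preference
        for u in corpus.users.values()
        if u.language_preference != "unknown"
    ]
    ages = [u.age_years for u in corpus.users.values() if u.age_years is not None]

    return CorpusSummary(
        n_users=len(corpus.users),
        n_inbound=n_in,
        n_outbound=n_out,
        n_total=len(corpus.messages),
        inbound_per_user_mean=mean,
        inbound_per_user_median=median,
        inbound_per_user_sd=sd,
        pct_female=(100.0 * sexes.count("female") / len(sexes)) if sexes else None,
        n_sex_known=len(sexes),
        pct_prefers_english=(100.0 * prefs.count("en") / len(prefs)) if prefs else None,
        n_pref_known=len(prefs),
        age_mean=statistics.fmean(ages) if ages else None,
        age_sd=(statistics.stdev(ages) if len(ages) > 1 else 0.0) if ages else None,
        n_age_known=len(ages),
    )


def export_term_counts(counts: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Privacy-preserving export filter for term-count tables.

    Keeps exactly the rows with tally ``n >= min_count`` (terms rarer than the
    threshold are withheld to guard against imperfect anonymization), ordered
    by descending tally then term.  ``counts`` needs columns ``term`` and
    ``n``; extra stratum columns pass through.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    for col in ("term", "n"):
        if col not in counts.columns:
            raise SchemaError(f"counts table missing column {col!r}")
    if (counts["n"] < 0).any():
        raise IntegrityError("negative tally in counts table")
    out = counts[counts["n"] >= min_count]
    return out.sort_values(["n", "term"], ascending=[False, True]).reset_index(
        drop=True
    )


def summary_to_dict(summary: CorpusSummary) -> dict:
    """Plain-dict view of a summary (JSON-friendly)."""
    return asdict(summary)


def utc(ts: str) -> datetime:
    """Parse an ISO timestamp, assuming UTC when no offset is given."""
    parsed = datetime.fromisoformat(ts)
    if parsed.tzinfo is None:
        parsed = parsed.replace(tzinfo=timezone.utc)
    return parsed
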
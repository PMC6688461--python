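"""Character n-gram naive Bayes language identification for short messages.

The classifier scores a message under per-language character n-gram models
(default 2–4-grams, additive smoothing) and returns the winning label together
with a per-character mean log-likelihood margin over the runner-up.  Margins
below a reliability threshold — including empty or non-alphabetic messages —
yield ``und`` (undetermined).  ``und`` labels on a user's inbound messages are
then imputed from the modal detected language of that user's other inbound
messages in the same ISO calendar week, the rule used when a detector cannot
label every message in a code-switching corpus.

The model is deliberately small (the two study languages plus ``und``) and
serializes to portable JSON.  An external detector can be plugged in anywhere
a ``detect(text) -> (label, score)`` callable is accepted.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Corpus, Message
from .errors import EmptyInputError, TrainingError

UND = "und"

_LETTERS = re.compile(r"[^\W\d_]+")

#: Margin (per character) below which a classification is deemed unreliable.
#: Near-random strings score ≈0 under both models; genuinely in-language text
#: of a few words clears this comfortably.
DEFAULT_RELIABILITY_THRESHOLD = 0.05


def _normalize_text(text: str) -> str:
    """Lowercase and reduce to letter runs joined by single spaces."""
    return " ".join(_LETTERS.findall(text.lower()))


def _char_ngrams(text: str, ngram_range: tuple[int, int]) -> list[str]:
    lo, hi = ngram_range
    grams: list[str] = []
    for n in range(lo, hi + 1):
        grams.extend(text[i : i + n] for i in range(len(text) - n + 1))
    return grams


@dataclass
class LanguageModel:
    """Per-language character n-gram log-probabilities.

    ``log_probs[lang]`` maps each observed n-gram to its smoothed
    log-probability; ``oov_log_prob[lang]`` is the (shared) log-probability of
    any unseen n-gram under the same additive-smoothing scheme, so the
    per-language distribution over the vocabulary plus one out-of-vocabulary
    bucket is proper.
    """

    languages: tuple[str, ...]
    ngram_range: tuple[int, int]
    smoothing: float
    log_probs: dict[str, dict[str, float]]
    oov_log_prob: dict[str, float]
    priors: dict[str, float]
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD
    format_version: int = 1

    def score(self, text: str) -> dict[str, float]:
        """Total log-likelihood (plus prior) of ``text`` per language."""
        norm = _normalize_text(text)
        grams = _char_ngrams(norm, self.ngram_range)
        scores = {}
        for lang in self.languages:
            table = self.log_probs[lang]
            oov = self.oov_log_prob[lang]
            scores[lang] = self.priors[lang] + sum(
                table.get(g, oov) for g in grams
            )
        return scores

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": self.format_version,
            "languages": list(self.languages),
            "ngram_range": list(self.ngram_range),
            "smoothing": self.smoothing,
            "log_probs": self.log_probs,
            "oov_log_prob": self.oov_log_prob,
            "priors": self.priors,
            "reliability_threshold": self.reliability_threshold,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LanguageModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            languages=tuple(payload["languages"]),
            ngram_range=tuple(payload["ngram_range"]),
            smoothing=payload["smoothing"],
            log_probs=payload["log_probs"],
            oov_log_prob=payload["oov_log_prob"],
            priors=payload["priors"],
            reliability_threshold=payload["reliability_threshold"],
            format_version=payload["format_version"],
        )


def train_language_model(
    labeled_texts: Iterable[tuple[str, str]],
    ngram_range: tuple[int, int] = (2, 4),
    smoothing: float = 0.5,
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
) -> LanguageModel:
    """Train the n-gram naive Bayes model from ``(text, label)`` pairs.

    Texts are lowercased and stripped to letter runs internally.  Every
    declared label must contribute at least one non-empty text.  Priors are
    uniform: in a code-switching corpus the training mix is not an estimate
    of the deployment mix, so the data decide alone.
    """
    if smoothing <= 0:
        raise TrainingError("smoothing must be positive")
    counts: dict[str, Counter] = {}
    for text, label in labeled_texts:
        counts.setdefault(label, Counter()).update(
            _char_ngrams(_normalize_text(text), ngram_range)
        )
    if not counts:
        raise TrainingError("no training texts supplied")
    for label, ctr in counts.items():
        if sum(ctr.values()) == 0:
            raise TrainingError(f"no usable training text for language {label!r}")

    vocab = set()
    for ctr in counts.values():
        vocab.update(ctr)
    v = len(vocab) + 1  # +1 out-of-vocabulary bucket

    languages = tuple(sorted(counts))
    log_probs: dict[str, dict[str, float]] = {}
    oov: dict[str, float] = {}
    for lang in languages:
        ctr = counts[lang]
        total = sum(ctr.values()) + smoothing * v
        log_probs[lang] = {
            g: math.log((ctr.get(g, 0) + smoothing) / total) for g in vocab
        }
        oov[lang] = math.log(smoothing / total)
    priors = {lang: -math.log(len(languages)) for lang in languages}
    return LanguageModel(
        languages=languages,
        ngram_range=ngram_range,
        smoothing=smoothing,
        log_probs=log_probs,
        oov_log_prob=oov,
        priors=priors,
        reliability_threshold=reliability_threshold,
    )


def detect_language(model: LanguageModel, text: str | None) -> tuple[str, float]:
    """Classify one message; total function, never raises.

    Returns ``(label, margin)`` where the margin is the per-character mean
    log-likelihood gap between the best and second-best language.  Empty
    text, text with no modeled n-grams, and margins below the model's
    reliability threshold all yield ``(und, margin)``.
    """
    if not text:
        return (UND, 0.0)
    norm = _normalize_text(text)
    if len(norm) < model.ngram_range[0]:
        return (UND, 0.0)
    scores = model.score(text)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_lang, best = ordered[0]
    second = ordered[1][1] if len(ordered) > 1 else -math.inf
    margin = (best - second) / len(norm)
    if margin < model.reliability_threshold:
        return (UND, margin)
    return (best_lang, margin)


def detect_corpus(
    corpus: Corpus, model: LanguageModel, directions: Sequence[str] = ("inbound",)
) -> Corpus:
    """Set ``message.language`` from the detector (in place; returns corpus)."""
    for m in corpus.messages:
        if m.direction in directions:
            m.language, _ = detect_language(model, m.body)
    return corpus


def _modal_label(labels: list[str]) -> str | None:
    """Most frequent non-und label; None on a tie or when none exist."""
    ctr = Counter(lab for lab in labels if lab and lab != UND)
    if not ctr:
        return None
    top = ctr.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None
    return top[0][0]


def impute_weekly_language(corpus: Corpus) -> Corpus:
    """Fill ``und`` labels from the user's weekly dominant language.

    Each inbound ``und`` message takes the modal detected (non-und) language
    among the same user's inbound messages of the same ISO week.  A weekly
    tie falls back to the user's overall dominant detected language; if that
    is also tied (or no detected message exists) the label stays ``und``.
    Non-und labels and outbound messages are never touched, so the operation
    is idempotent.
    """
    by_user_week: dict[tuple[str, int, int], list[Message]] = {}
    by_user: dict[str, list[str]] = {}
    for m in corpus.messages:
        if m.direction != "inbound":
            continue
        year, week = m.iso_week()
        by_user_week.setdefault((m.user_id, year, week), []).append(m)
        by_user.setdefault(m.user_id, []).append(m.language or UND)

    for (user_id, _, _), msgs in by_user_week.items():
        week_modal = _modal_label([m.language or UND for m in msgs])
        label = week_modal
        if label is None:
            label = _modal_label(by_user[user_id])
        if label is None:
            continue
        for m in msgs:
            if m.language == UND or m.language is None:
                m.language = label
    return corpus


def language_mix(corpus: Corpus) -> dict[str, float]:
    """Percent shares of inbound messages by final label (en/sw/und)."""
    inbound = corpus.inbound()
    if not inbound:
        raise EmptyInputError("corpus has no inbound messages")
    ctr = Counter((m.language or UND) for m in inbound)
    n = len(inbound)
    return {lang: 100.0 * ctr.get(lang, 0) / n for lang in ("en", "sw", UND)}


@dataclass
class DiscordanceReport:
    """Mismatch between stated language preference and detected language.

    Denominators include only inbound messages with a determined final label
    from users with a known preference.  ``defined`` is False when no such
    message exists.
    """

    pct_messages_discordant: float | None
    pct_users_any_discordant: float | None
    n_messages: int = 0
    n_users: int = 0
    defined: bool = True


def discordance(corpus: Corpus) -> DiscordanceReport:
    """Message- and user-level preference/detection discordance."""
    n_msgs = 0
    n_disc = 0
    user_any: dict[str, bool] = {}
    for m in corpus.inbound():
        user = corpus.users.get(m.user_id)
        if user is None or user.language_preference == "unknown":
            continue
        if m.language in (None, UND):
            continue
        n_msgs += 1
        disc = m.language != user.language_preference
        n_disc += disc
        user_any[m.user_id] = user_any.get(m.user_id, False) or disc
    if n_msgs == 0:
        return DiscordanceReport(None, None, 0, 0, defined=False)
    return DiscordanceReport(
        pct_messages_discordant=100.0 * n_disc / n_msgs,
        pct_users_any_discordant=100.0 * sum(user_any.values()) / len(user_any),
        n_messages=n_msgs,
        n_users=len(user_any),
    )
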
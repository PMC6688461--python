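"""Token normalization: tokenize, spell-correct, lemmatize, merge, filter.

The normalization pipeline runs in a fixed, documented order:

    tokenize -> spell-correct -> lemmatize -> collapse synonyms
             -> (bigram preemption, see :mod:`chatmine.frequency`)
             -> stop-word filter

Spell correction follows a conservative frequency-thresholded policy: a
suggestion is accepted only for tokens that are *rare* in the corpus (fewer
than ``max_count_exclusive`` occurrences, default 4) and only for languages
where suggestions are enabled (default English only — no Swahili token is
ever corrected).  The suggestion source is pluggable; the shipped default is
an offline edit-distance-1 lookup against a packaged English wordlist.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError, SchemaError

_APOSTROPHES = re.compile(r"[’']")
_LETTER_RUNS = re.compile(r"[^\W\d_]+")
_ALNUM_RUNS = re.compile(r"[^\W_]+")


def tokenize(body: str | None, alphanumeric: bool = False) -> list[str]:
    """Split a message body into lowercase tokens.

    Tokens are maximal runs of Unicode letters; punctuation and digits are
    stripped, and apostrophes are removed with the halves joined
    (``don't`` -> ``dont``).  With ``alphanumeric=True``, digits are kept
    inside tokens so brand-like terms such as ``p2`` survive.
    """
    if not body:
        return []
    text = _APOSTROPHES.sub("", body.lower())
    pattern = _ALNUM_RUNS if alphanumeric else _LETTER_RUNS
    return pattern.findall(text)


@dataclass(frozen=True)
class StopList:
    """A stop-word list for one language, tagged with its source lexicon."""

    language: str
    words: frozenset[str]
    source: str = "custom"

    def __post_init__(self) -> None:
        for w in self.words:
            if w != w.lower() or any(ch.isspace() for ch in w):
                raise ConfigurationError(f"invalid stop word {w!r}")


def load_stoplist(path: str | Path) -> list[StopList]:
    """Read stop lists from a CSV with columns word, language, source."""
    groups: dict[tuple[str, str], set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "word" not in reader.fieldnames:
            raise SchemaError("stop list missing required column 'word'")
        for row in reader:
            key = (row.get("language") or "en", row.get("source") or "custom")
            groups.setdefault(key, set()).add(row["word"].strip().lower())
    return [
        StopList(language=lang, words=frozenset(words), source=src)
        for (lang, src), words in sorted(groups.items())
    ]


def stopword_set(stoplists: Iterable[StopList]) -> frozenset[str]:
    out: set[str] = set()
    for sl in stoplists:
        out.update(sl.words)
    return frozenset(out)


def filter_stopwords(tokens: Sequence[str], stoplists: Iterable[StopList]) -> list[str]:
    """Drop tokens present in any supplied stop list, preserving order."""
    stops = stopword_set(stoplists)
    return [t for t in tokens if t not in stops]


@dataclass(frozen=True)
class SpellPolicy:
    """Frequency-thresholded spell-correction policy.

    A suggestion is accepted only when a token's corpus count is strictly
    below ``max_count_exclusive`` and the token's language is in
    ``languages_enabled``.
    """

    max_count_exclusive: int = 4
    languages_enabled: frozenset[str] = frozenset({"en"})

    def __post_init__(self) -> None:
        if self.max_count_exclusive < 1:
            raise ConfigurationError("max_count_exclusive must be >= 1")


Suggester = Callable[[str], list[str]]


class EditDistanceSuggester:
    """Offline suggestion source: edit-distance-1 matches in a wordlist.

    Returns no suggestion for in-vocabulary tokens (nothing to fix) and the
    alphabetically first edit-distance-1 dictionary neighbours otherwise.
    """

    _ALPHABET = "abcdefghijklmnopqrstuvwxyz"

    def __init__(self, wordlist: Iterable[str]):
        self.words = frozenset(w.strip().lower() for w in wordlist if w.strip())

    def _edits1(self, word: str) -> set[str]:
        splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
        deletes = {a + b[1:] for a, b in splits if b}
        transposes = {a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1}
        replaces = {a + c + b[1:] for a, b in splits if b for c in self._ALPHABET}
        inserts = {a + c + b for a, b in splits for c in self._ALPHABET}
        return deletes | transposes | replaces | inserts

    def __call__(self, word: str) -> list[str]:
        if word in self.words:
            return []
        return sorted(self._edits1(word) & self.words)


def build_correction_map(
    corpus_token_counts: Mapping[str, int],
    suggester: Suggester,
    policy: SpellPolicy = SpellPolicy(),
    language: str = "en",
) -> dict[str, str]:
    """Map each corpus token to its correction (or itself).

    A token maps to the first suggestion iff its count is below the policy
    threshold, suggestions are enabled for ``language``, and the suggester
    offers one; every other token maps to itself, so applying the map is a
    pure substitution that conserves token count.
    """
    out: dict[str, str] = {}
    enabled = language in policy.languages_enabled
    for token, count in corpus_token_counts.items():
        correction = token
        if enabled and count < policy.max_count_exclusive:
            suggestions = suggester(token)
            if suggestions:
                correction = suggestions[0]
        out[token] = correction
    return out


def apply_correction_map(tokens: Sequence[str], corrections: Mapping[str, str]) -> list[str]:
    return [corrections.get(t, t) for t in tokens]


def load_lemma_table(path: str | Path) -> dict[str, str]:
    """Read an inflected→lemma CSV; validates idempotence.

    A table where some lemma is itself re-mapped (``a→b`` and ``b→c``) is
    rejected, so ``lemmatize`` applied twice equals once by construction.
    """
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "inflected" not in reader.fieldnames:
            raise SchemaError("lemma table missing required column 'inflected'")
        for row in reader:
            table[row["inflected"].strip().lower()] = row["lemma"].strip().lower()
    for inflected, lemma in table.items():
        if lemma in table and table[lemma] != lemma:
            raise ConfigurationError(
                f"lemma table not idempotent: {inflected!r} -> {lemma!r} -> {table[lemma]!r}"
            )
    return table


def lemmatize(tokens: Sequence[str], table: Mapping[str, str]) -> list[str]:
    """Replace each token by its lemma; unknown tokens pass through."""
    return [table.get(t, t) for t in tokens]


@dataclass(frozen=True)
class SynonymMap:
    """Variant→canonical merges (e.g. ``menses`` -> ``period``).

    Chains and cycles are configuration errors: every canonical label must
    map to itself or be absent from the variant keys, which makes
    application idempotent.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for variant, canonical in self.entries.items():
            nxt = self.entries.get(canonical, canonical)
            if nxt != canonical:
                raise ConfigurationError(
                    f"synonym chain: {variant!r} -> {canonical!r} -> {nxt!r}"
                )


def load_synonym_map(path: str | Path) -> SynonymMap:
    """Read a variant,canonical CSV (the archived modifications dialect)."""
    entries: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "variant" not in reader.fieldnames:
            raise SchemaError("synonym map missing required column 'variant'")
        for row in reader:
            entries[row["variant"].strip().lower()] = row["canonical"].strip().lower()
    return SynonymMap(entries=entries)


def collapse_synonyms(tokens: Sequence[str], synonyms: SynonymMap) -> list[str]:
    """Replace mapped variants by their canonical label; length preserved."""
    return [synonyms.entries.get(t, t) for t in tokens]


def normalize_stream(
    body: str | None,
    corrections: Mapping[str, str] | None = None,
    lemma_table: Mapping[str, str] | None = None,
    synonyms: SynonymMap | None = None,
    alphanumeric: bool = False,
) -> list[str]:
    """Tokenize and normalize one message (stop filtering happens later,
    after bigram preemption)."""
    tokens = tokenize(body, alphanumeric=alphanumeric)
    if corrections:
        tokens = apply_correction_map(tokens, corrections)
    if lemma_table:
        tokens = lemmatize(tokens, lemma_table)
    if synonyms:
        tokens = collapse_synonyms(tokens, synonyms)
    return tokens
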
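"""Bigram-preemption tallying and stratified term-frequency tables.

A *key bigram* is an adjacent token pair treated as a single countable term
("family planning", "side effects").  Under preemption, a greedy
left-to-right scan emits the bigram and consumes both tokens whenever a key
pair occurs; tokens not consumed by a bigram are counted individually (after
stop-word filtering).  So "family" inside "family planning" tallies to the
bigram, while a lone "family" tallies as a word — the two never double count.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Corpus
from .errors import ParameterError
from .normalize import StopList, stopword_set

#: Default age bands for sex×age stratification; upper bound None = open.
DEFAULT_AGE_BANDS: tuple[tuple[int, int | None], ...] = (
    (15, 19),
    (20, 24),
    (25, 35),
    (36, None),
)

TokenStream = Sequence[str]


def discover_key_bigrams(
    streams: Iterable[TokenStream],
    top_k: int = 25,
    min_count: int = 5,
    stoplists: Iterable[StopList] = (),
) -> list[tuple[str, str]]:
    """Most frequent adjacent token pairs, excluding pairs with stop words.

    Returns at most ``top_k`` pairs with count >= ``min_count``, ordered by
    count descending then lexicographically (ties at the cut are resolved
    lexicographically, so the result is deterministic).
    """
    stops = stopword_set(stoplists)
    ctr: Counter = Counter()
    for stream in streams:
        for a, b in zip(stream, stream[1:]):
            if a not in stops and b not in stops:
                ctr[(a, b)] += 1
    eligible = [(pair, n) for pair, n in ctr.items() if n >= min_count]
    eligible.sort(key=lambda item: (-item[1], item[0]))
    return [pair for pair, _ in eligible[:top_k]]


def adjacent_pair_counts(streams: Iterable[TokenStream]) -> pd.DataFrame:
    """Raw adjacency counts over all consecutive token pairs.

    This is the pre-preemption pair table consumed by
    :func:`chatmine.association.bigram_edges`.
    """
    ctr: Counter = Counter()
    for stream in streams:
        ctr.update(zip(stream, stream[1:]))
    rows = sorted(ctr.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(
        [(a, b, n) for (a, b), n in rows], columns=["term_a", "term_b", "n"]
    )


def preempt_stream(
    stream: TokenStream, key_bigrams: Iterable[tuple[str, str]]
) -> list[str]:
    """Greedy left-to-right tiling of one stream.

    When the pair at the cursor is a key bigram, emit it (rendered with a
    single space) and advance by two; otherwise emit the single token and
    advance by one.  Pairings never overlap.
    """
    keys = set(key_bigrams)
    out: list[str] = []
    i = 0
    n = len(stream)
    while i < n:
        if i + 1 < n and (stream[i], stream[i + 1]) in keys:
            out.append(f"{stream[i]} {stream[i + 1]}")
            i += 2
        else:
            out.append(stream[i])
            i += 1
    return out


def tally_with_preemption(
    message_streams: Iterable[TokenStream],
    key_bigrams: Iterable[tuple[str, str]] = (),
    stoplists: Iterable[StopList] = (),
) -> pd.DataFrame:
    """Aggregate term counts under bigram preemption.

    Bigram terms are counted as emitted; single tokens are stop-word
    filtered after pairing (key bigrams themselves must not contain stop
    words, which :func:`discover_key_bigrams` guarantees).
    """
    keys = set(key_bigrams)
    stops = stopword_set(stoplists)
    ctr: Counter = Counter()
    for stream in message_streams:
        for term in preempt_stream(stream, keys):
            if " " in term or term not in stops:
                ctr[term] += 1
    rows = sorted(ctr.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(rows, columns=["term", "n"])


def age_band_label(age: float | None, bands: Sequence[tuple[int, int | None]]) -> str:
    if age is None:
        return "missing"
    for lo, hi in bands:
        if age >= lo and (hi is None or age <= hi):
            return f"{lo}+" if hi is None else f"{lo}-{hi}"
    return "missing"


def _stratum_of(user, spec: str, bands) -> str:
    if spec == "sex":
        return user.sex if user.sex != "unknown" else "missing"
    if spec == "sex_age":
        sex = user.sex if user.sex != "unknown" else "missing"
        band = age_band_label(user.age_years, bands)
        return f"{sex}|{band}" if "missing" not in (sex, band) else "missing"
    raise ParameterError(f"unknown strata_spec {spec!r}")


def stratified_counts(
    corpus: Corpus,
    streams: Mapping[str, TokenStream],
    strata_spec: str = "none",
    key_bigrams: Iterable[tuple[str, str]] = (),
    stoplists: Iterable[StopList] = (),
    age_bands: Sequence[tuple[int, int | None]] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Preemption tallies per stratum (``none``/``sex``/``sex_age``/``language``).

    ``streams`` maps message_id to that message's normalized token stream
    (messages absent from the mapping are skipped).  Users whose stratum
    attribute is unknown are pooled under ``missing``, so stratified counts
    always marginalize exactly to the pooled tally.
    """
    if strata_spec not in ("none", "sex", "sex_age", "language"):
        raise ParameterError(f"unknown strata_spec {strata_spec!r}")
    groups: dict[str, list[TokenStream]] = {}
    for m in corpus.inbound():
        if m.message_id not in streams:
            continue
        if strata_spec == "none":
            stratum = "all"
        elif strata_spec == "language":
            stratum = m.language or "und"
        else:
            stratum = _stratum_of(corpus.users[m.user_id], strata_spec, age_bands)
        groups.setdefault(stratum, []).append(streams[m.message_id])

    frames = []
    for stratum in sorted(groups):
        tally = tally_with_preemption(groups[stratum], key_bigrams, stoplists)
        tally.insert(1, "stratum", stratum)
        frames.append(tally)
    if not frames:
        return pd.DataFrame(columns=["term", "stratum", "n"])
    return pd.concat(frames, ignore_index=True)


def forced_rank(counts_by_stratum: pd.DataFrame, top_n: int = 25) -> pd.DataFrame:
    """Rank terms 1..N within each stratum with no ties.

    Ordering is count descending, ties broken lexicographically, so each
    rank in 1..N is used exactly once per stratum.
    """
    if "stratum" not in counts_by_stratum.columns:
        counts_by_stratum = counts_by_stratum.assign(stratum="all")
    rows = []
    for stratum, grp in counts_by_stratum.groupby("stratum", sort=True):
        grp = grp.sort_values(["n", "term"], ascending=[False, True]).head(top_n)
        for rank, (_, row) in enumerate(grp.iterrows(), start=1):
            rows.append((stratum, row["term"], rank, int(row["n"])))
    return pd.DataFrame(rows, columns=["stratum", "term", "rank", "n"])
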
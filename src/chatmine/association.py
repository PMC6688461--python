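"""Word-association statistics: directed bigram edges and pairwise phi.

The phi coefficient between two terms is the Pearson correlation of their
binary presence indicators over *sections* (by default, one section per user:
all of a user's inbound messages of one language pooled).  From the 2x2
presence table with cells n11 (both), n10 (a only), n01 (b only), n00
(neither):

    phi = (n11*n00 - n10*n01) / sqrt((n11+n10)(n01+n00)(n11+n01)(n10+n00))

Pairs with a zero denominator (a term present in every or no section) carry
no information and are omitted.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .errors import EmptyInputError
from .normalize import StopList, stopword_set


def bigram_edges(
    adjacent_pair_counts: pd.DataFrame,
    min_count: int = 3,
    stoplists: Iterable[StopList] = (),
) -> pd.DataFrame:
    """Directed word-adjacency edges with a minimum-count filter.

    Input is the raw pre-preemption pair table (columns term_a, term_b, n);
    the edge direction means "term_a immediately preceded term_b".  Pairs
    containing a stop word are excluded.  Output columns: from, to, n.
    """
    stops = stopword_set(stoplists)
    df = adjacent_pair_counts
    keep = (
        (df["n"] >= min_count)
        & ~df["term_a"].isin(stops)
        & ~df["term_b"].isin(stops)
    )
    out = df.loc[keep, ["term_a", "term_b", "n"]].rename(
        columns={"term_a": "from", "term_b": "to"}
    )
    return out.sort_values(["n", "from", "to"], ascending=[False, True, True]).reset_index(
        drop=True
    )


def phi_from_table(n11: int, n10: int, n01: int, n00: int) -> float | None:
    """Phi from the 2x2 presence counts; None on a zero denominator."""
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def pairwise_phi(
    section_term_presence: Iterable[Iterable[str]],
    min_section_occurrences: int = 20,
) -> pd.DataFrame:
    """Phi for every pair of sufficiently common terms.

    ``section_term_presence`` yields, per section, the set of terms present.
    Terms appearing in fewer than ``min_section_occurrences`` sections are
    dropped (phi is unstable for rare terms).  Output columns: term_a,
    term_b, phi, n_sections, with term_a < term_b; phi is symmetric, so each
    unordered pair appears once.
    """
    sections = [frozenset(s) for s in section_term_presence]
    n = len(sections)
    if n < 2:
        raise EmptyInputError("pairwise_phi needs at least 2 sections")

    doc_freq: dict[str, int] = {}
    for s in sections:
        for t in s:
            doc_freq[t] = doc_freq.get(t, 0) + 1
    terms = sorted(t for t, f in doc_freq.items() if f >= min_section_occurrences)
    if len(terms) < 2:
        return pd.DataFrame(columns=["term_a", "term_b", "phi", "n_sections"])

    index = {t: i for i, t in enumerate(terms)}
    presence = np.zeros((len(terms), n), dtype=np.int64)
    for j, s in enumerate(sections):
        for t in s:
            i = index.get(t)
            if i is not None:
                presence[i, j] = 1

    both = presence @ presence.T  # n11 for every pair
    totals = presence.sum(axis=1)
    rows = []
    for i, j in itertools.combinations(range(len(terms)), 2):
        n11 = int(both[i, j])
        n10 = int(totals[i]) - n11
        n01 = int(totals[j]) - n11
        n00 = n - n11 - n10 - n01
        phi = phi_from_table(n11, n10, n01, n00)
        if phi is not None:
            rows.append((terms[i], terms[j], phi, n))
    out = pd.DataFrame(rows, columns=["term_a", "term_b", "phi", "n_sections"])
    return out.sort_values(
        ["phi", "term_a", "term_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def user_sections(
    corpus: Corpus,
    streams: Mapping[str, Sequence[str]],
    language: str | None = "en",
    stoplists: Iterable[StopList] = (),
) -> list[set[str]]:
    """Build per-user term-presence sections for :func:`pairwise_phi`.

    Pools each user's inbound messages (optionally restricted to one final
    language label), applying stop-word filtering at the section level.
    """
    stops = stopword_set(stoplists)
    per_user: dict[str, set[str]] = {}
    for m in corpus.inbound():
        if language is not None and m.language != language:
            continue
        tokens = streams.get(m.message_id)
        if tokens is None:
            continue
        per_user.setdefault(m.user_id, set()).update(
            t for t in tokens if t not in stops
        )
    return [per_user[u] for u in sorted(per_user)]
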
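"""End-to-end convenience pipeline over a loaded corpus.

Chains the per-module operations in the documented order: language
detection → weekly imputation → normalization (tokenize, spell-correct,
lemmatize, collapse synonyms) → bigram discovery and preemption tallies →
stratified counts and forced ranks → associations → engagement.  Each stage
is also available individually from its own module; this wrapper exists so
examples, tests and the acceptance script share one code path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import resources
from .association import bigram_edges, pairwise_phi, user_sections
from .corpus import Corpus, CorpusSummary, summarize_corpus
from .engagement import classify_engagement, single_message_rate_ratio
from .frequency import (
    adjacent_pair_counts,
    discover_key_bigrams,
    forced_rank,
    stratified_counts,
    tally_with_preemption,
)
from .langid import (
    DiscordanceReport,
    detect_corpus,
    discordance,
    impute_weekly_language,
    language_mix,
)
from .normalize import SpellPolicy, build_correction_map, normalize_stream


@dataclass
class PipelineResult:
    summary: CorpusSummary
    language_mix: dict[str, float]
    discordance: DiscordanceReport
    engagement_records: pd.DataFrame
    engagement_shares: dict[str, float]
    single_message_sex_ratio: float | None
    key_bigrams: list[tuple[str, str]]
    term_counts: pd.DataFrame
    counts_by_sex_age: pd.DataFrame
    ranks_by_sex_age: pd.DataFrame
    bigram_edges: pd.DataFrame
    phi: pd.DataFrame
    streams: dict[str, list[str]] = field(repr=False, default_factory=dict)


def analyze_corpus(
    corpus: Corpus,
    model=None,
    spell_policy: SpellPolicy = SpellPolicy(),
    top_k_bigrams: int = 25,
    bigram_min_count: int = 5,
    edge_min_count: int = 10,
    phi_min_sections: int = 20,
    rank_top_n: int = 25,
) -> PipelineResult:
    """Run the full analysis on ``corpus`` (mutates message languages)."""
    model = model or resources.default_language_model()
    detect_corpus(corpus, model)
    impute_weekly_language(corpus)

    stoplists = resources.english_stoplists() + resources.swahili_stoplists()
    english = [m for m in corpus.inbound() if m.language == "en"]

    # corpus-wide token counts drive the frequency-thresholded spell policy
    raw_counts: Counter = Counter()
    raw_tokens: dict[str, list[str]] = {}
    for m in english:
        from .normalize import tokenize

        toks = tokenize(m.body)
        raw_tokens[m.message_id] = toks
        raw_counts.update(toks)
    corrections = build_correction_map(
        raw_counts, resources.default_suggester(), spell_policy
    )
    lemma = resources.default_lemma_table()
    synonyms = resources.default_synonym_map()
    streams = {
        mid: normalize_stream(
            " ".join(toks), corrections=corrections, lemma_table=lemma, synonyms=synonyms
        )
        for mid, toks in raw_tokens.items()
    }

    key_bigrams = discover_key_bigrams(
        streams.values(), top_k=top_k_bigrams, min_count=bigram_min_count, stoplists=stoplists
    )
    term_counts = tally_with_preemption(streams.values(), key_bigrams, stoplists)
    by_cohort = stratified_counts(
        corpus, streams, strata_spec="sex_age", key_bigrams=key_bigrams, stoplists=stoplists
    )
    ranks = forced_rank(by_cohort, top_n=rank_top_n)

    pairs = adjacent_pair_counts(streams.values())
    edges = bigram_edges(pairs, min_count=edge_min_count, stoplists=stoplists)
    sections = user_sections(corpus, streams, language="en", stoplists=stoplists)
    phi = (
        pairwise_phi(sections, min_section_occurrences=phi_min_sections)
        if len(sections) >= 2
        else pd.DataFrame(columns=["term_a", "term_b", "phi", "n_sections"])
    )

    records, shares = classify_engagement(corpus)
    try:
        ratio = single_message_rate_ratio(records, corpus.users)
    except Exception:
        ratio = None

    return PipelineResult(
        summary=summarize_corpus(corpus),
        language_mix=language_mix(corpus),
        discordance=discordance(corpus),
        engagement_records=records,
        engagement_shares=shares,
        single_message_sex_ratio=ratio,
        key_bigrams=key_bigrams,
        term_counts=term_counts,
        counts_by_sex_age=by_cohort,
        ranks_by_sex_age=ranks,
        bigram_edges=edges,
        phi=phi,
        streams=streams,
    )


def recover_parameters(config, corpus=None, result: PipelineResult | None = None):
    """Run the pipeline on a generated corpus and compare recovered
    quantities against the generator configuration.

    Returns ``(report, result)`` where the report is the configured-vs-
    recovered table with 99% intervals.  Shares whose sampling variance is
    driven by per-user draws (language, engagement, demographics) use the
    user count as the effective sample size — messages from one user are
    clustered, not independent.
    """
    from .synthetic import generate_corpus, recovery_report

    if corpus is None:
        corpus, _ = generate_corpus(config)
    if result is None:
        result = analyze_corpus(corpus)

    s = result.summary
    n_users = config.n_users
    recovered: dict[str, float] = {}
    ns: dict[str, int] = {}

    recovered["female_share"] = (s.pct_female or 0.0) / 100.0
    ns["female_share"] = s.n_sex_known
    recovered["english_pref_share"] = (s.pct_prefers_english or 0.0) / 100.0
    ns["english_pref_share"] = s.n_pref_known
    recovered["age_mean"] = s.age_mean or float("nan")
    recovered["age_sd"] = s.age_sd or float("nan")
    ns["age_mean"] = ns["age_sd"] = s.n_age_known

    mix = result.language_mix
    labeled = mix["en"] + mix["sw"]
    recovered["english_share_labeled"] = mix["en"] / labeled if labeled else float("nan")
    ns["english_share_labeled"] = n_users

    disc = result.discordance
    if disc.defined:
        recovered["discordance"] = disc.pct_messages_discordant / 100.0
        ns["discordance"] = disc.n_users
    for pattern, pct in result.engagement_shares.items():
        recovered[pattern] = pct / 100.0
        ns[pattern] = len(result.engagement_records)
    if result.single_message_sex_ratio is not None:
        recovered["single_message_sex_ratio"] = result.single_message_sex_ratio
        ns["single_message_sex_ratio"] = s.n_sex_known

    ranks = result.ranks_by_sex_age
    for term, (sex, band) in config.planted_terms.items():
        stratum = f"{sex}|{band}"
        hit = ranks[(ranks["stratum"] == stratum) & (ranks["term"] == term)]
        recovered[f"planted_rank:{term}"] = (
            float(hit["rank"].iloc[0]) if len(hit) else float("nan")
        )
        ns[f"planted_rank:{term}"] = 1

    return recovery_report(config, recovered, ns), result
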
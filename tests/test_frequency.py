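"""Bigram preemption, stratified counts, forced ranking."""

import numpy as np
import pandas as pd
import pytest

from chatmine.errors import ParameterError
from chatmine.frequency import (
    adjacent_pair_counts,
    discover_key_bigrams,
    forced_rank,
    preempt_stream,
    stratified_counts,
    tally_with_preemption,
)
from chatmine.normalize import StopList

from conftest import msg, user

STOP_IS = (StopList(language="en", words=frozenset({"is"})),)


def greedy_tiling_oracle(stream, keys):
    """Independent oracle: enumerate all non-overlapping tilings, then select
    the one whose bigram start positions are lexicographically earliest
    (padded with infinity) — the defining property of the greedy scan."""
    stream = list(stream)
    keys = set(keys)

    def tilings(i):
        if i >= len(stream):
            yield ((), ())
            return
        for emis, starts in tilings(i + 1):
            yield ((stream[i],) + emis, starts)
        if i + 1 < len(stream) and (stream[i], stream[i + 1]) in keys:
            for emis, starts in tilings(i + 2):
                yield ((f"{stream[i]} {stream[i + 1]}",) + emis, (i,) + starts)

    def sort_key(item):
        _, starts = item
        return tuple(starts) + (float("inf"),) * (len(stream) - len(starts))

    best = min(tilings(0), key=sort_key)
    return list(best[0])


class TestPreemption:
    def test_bigram_preempts_but_lone_token_counts_alone(self):
        tally = tally_with_preemption(
            [["family", "planning", "is", "family", "business"]],
            key_bigrams=[("family", "planning")],
            stoplists=STOP_IS,
        )
        assert dict(zip(tally["term"], tally["n"])) == {
            "family planning": 1,
            "family": 1,
            "business": 1,
        }

    def test_repeated_bigram_counts_each_occurrence(self):
        tally = tally_with_preemption(
            [["side", "effects", "side", "effects"]],
            key_bigrams=[("side", "effects")],
        )
        assert dict(zip(tally["term"], tally["n"])) == {"side effects": 2}

    def test_greedy_never_overlaps(self):
        assert preempt_stream(["a", "a", "a"], [("a", "a")]) == ["a a", "a"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_tiling_oracle_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        keys = [("a", "b"), ("b", "a"), ("c", "c")]
        for _ in range(200):
            stream = list(rng.choice(list("abcd"), size=rng.integers(0, 12)))
            assert preempt_stream(stream, keys) == greedy_tiling_oracle(stream, keys)

    def test_token_conservation(self):
        rng = np.random.default_rng(42)
        keys = [("a", "b"), ("c", "c")]
        for _ in range(200):
            stream = list(rng.choice(list("abcd"), size=rng.integers(0, 15)))
            emitted = preempt_stream(stream, keys)
            singles = sum(1 for t in emitted if " " not in t)
            bigrams = sum(1 for t in emitted if " " in t)
            assert singles + 2 * bigrams == len(stream)


class TestDiscoverKeyBigrams:
    def test_frequent_pair_found(self):
        streams = [["family", "planning"]] * 10 + [["other", "words"]]
        assert discover_key_bigrams(streams, top_k=5, min_count=5) == [
            ("family", "planning")
        ]

    def test_empty_corpus(self):
        assert discover_key_bigrams([], top_k=5, min_count=1) == []

    def test_pairs_with_stop_words_excluded(self):
        streams = [["this", "is", "planning"]] * 10
        got = discover_key_bigrams(streams, top_k=5, min_count=1, stoplists=STOP_IS)
        assert ("is", "planning") not in got and ("this", "is") not in got

    def test_tie_at_cut_resolved_lexicographically(self):
        streams = [["b", "b"], ["a", "a"]] * 3
        assert discover_key_bigrams(streams, top_k=1, min_count=1) == [("a", "a")]


class TestStratified:
    def fixture(self, make_corpus):
        corpus = make_corpus(
            [msg(1, "f1"), msg(2, "m1")],
            users=[user("f1", sex="female", age=22), user("m1", sex="male", age=22)],
        )
        streams = {"m1": ["sex"], "m2": ["sex"]}
        return corpus, streams

    def test_by_sex_hand_tally(self, make_corpus):
        corpus, streams = self.fixture(make_corpus)
        out = stratified_counts(corpus, streams, strata_spec="sex")
        assert set(zip(out["term"], out["stratum"], out["n"])) == {
            ("sex", "female", 1),
            ("sex", "male", 1),
        }

    def test_none_equals_unstratified(self, make_corpus):
        corpus, streams = self.fixture(make_corpus)
        pooled = stratified_counts(corpus, streams, strata_spec="none")
        direct = tally_with_preemption(streams.values())
        assert dict(zip(pooled["term"], pooled["n"])) == dict(
            zip(direct["term"], direct["n"])
        )

    def test_strata_marginalize_to_pooled(self, make_corpus):
        corpus, streams = self.fixture(make_corpus)
        by_sex = stratified_counts(corpus, streams, strata_spec="sex")
        pooled = stratified_counts(corpus, streams, strata_spec="none")
        marg = by_sex.groupby("term")["n"].sum().to_dict()
        assert marg == dict(zip(pooled["term"], pooled["n"]))

    def test_unknown_spec_rejected(self, make_corpus):
        corpus, streams = self.fixture(make_corpus)
        with pytest.raises(ParameterError):
            stratified_counts(corpus, streams, strata_spec="shoe_size")

    def test_unknown_attributes_pool_under_missing(self, make_corpus):
        corpus = make_corpus([msg(1, "x")], users=[user("x")])
        out = stratified_counts(corpus, {"m1": ["hello"]}, strata_spec="sex")
        assert list(out["stratum"]) == ["missing"]


class TestForcedRank:
    def test_tie_broken_lexicographically(self):
        counts = pd.DataFrame(
            {"term": ["love", "sex"], "stratum": ["all", "all"], "n": [10, 10]}
        )
        out = forced_rank(counts, top_n=5)
        assert list(zip(out["term"], out["rank"])) == [("love", 1), ("sex", 2)]

    def test_single_term_rank_one(self):
        out = forced_rank(pd.DataFrame({"term": ["a"], "n": [1]}), top_n=5)
        assert list(out["rank"]) == [1]

    def test_ranks_are_a_permutation_within_each_stratum(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {
                "term": [f"t{i}" for i in range(30)] * 2,
                "stratum": ["a"] * 30 + ["b"] * 30,
                "n": rng.integers(1, 5, size=60),
            }
        )
        out = forced_rank(counts, top_n=10)
        for _, grp in out.groupby("stratum"):
            assert sorted(grp["rank"]) == list(range(1, 11))


def test_adjacent_pair_counts_counts_every_consecutive_pair():
    out = adjacent_pair_counts([["a", "b", "a", "b"]])
    got = {(r.term_a, r.term_b): r.n for r in out.itertuples()}
    assert got == {("a", "b"): 2, ("b", "a"): 1}
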
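"""Frequency analysis: normalization, bigram preemption, cohort ranks.

Runs the full normalization chain (tokenize, frequency-thresholded spell
correction, lemmas, synonym merges), discovers key bigrams, tallies terms
under preemption and prints forced ranks by sex and age band.
"""

from chatmine.pipeline import analyze_corpus
from chatmine.synthetic import GeneratorConfig, generate_corpus

corpus, _ = generate_corpus(GeneratorConfig(n_users=3000, seed=11))
result = analyze_corpus(corpus)

print("key bigrams discovered:", [" ".join(p) for p in result.key_bigrams[:8]])
print("\ntop terms (bigram preemption, stop words removed):")
print(result.term_counts.head(10).to_string(index=False))

ranks = result.ranks_by_sex_age
for stratum in ("female|15-19", "male|36+"):
    top = ranks[ranks["stratum"] == stratum].head(5)
    print(f"\ntop 5 terms, {stratum} (forced rank, no ties):")
    print(top[["rank", "term", "n"]].to_string(index=False))
# the oldest-male cohort surfaces its own vocabulary (e.g. prostate) that
# never tops the ranks of younger or female cohorts
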
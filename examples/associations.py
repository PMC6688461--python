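"""Word associations: directed bigram edges and pairwise phi.

Edges count how often one word immediately precedes another; phi measures
whether two words co-occur in the same users' message sets more or less
often than chance (it is the Pearson correlation of the presence
indicators over users).
"""

from chatmine.pipeline import analyze_corpus
from chatmine.synthetic import GeneratorConfig, generate_corpus

corpus, _ = generate_corpus(GeneratorConfig(n_users=3000, seed=23))
result = analyze_corpus(corpus)

print("strongest directed adjacencies (from -> to, count):")
print(result.bigram_edges.head(8).to_string(index=False))

print("\nstrongest phi correlations over user sections:")
print(result.phi.head(8).to_string(index=False))
print("\nphi near +1: the words travel together across users; near 0: independent")
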
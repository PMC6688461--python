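"""Generate a synthetic chat corpus and print its headline descriptives.

The generator emulates a two-way SMS health service: a mostly-female,
young user base, heavy-tailed per-user message counts, agent replies, and
English/Swahili code-switching.
"""

from chatmine.corpus import summarize_corpus
from chatmine.engagement import classify_engagement, single_message_rate_ratio, weekly_volume
from chatmine.synthetic import GeneratorConfig, generate_corpus

config = GeneratorConfig(n_users=2000, seed=42)
corpus, truth = generate_corpus(config)

s = summarize_corpus(corpus)
print(f"{s.n_users} users, {s.n_inbound} inbound + {s.n_outbound} outbound = {s.n_total} messages")
print(f"inbound per user: median {s.inbound_per_user_median}, mean {s.inbound_per_user_mean:.2f}")
print(f"female {s.pct_female:.1f}% (of {s.n_sex_known} with known sex), "
      f"prefers English {s.pct_prefers_english:.1f}%, "
      f"age {s.age_mean:.1f} (SD {s.age_sd:.1f})")

records, shares = classify_engagement(corpus)
print("\nengagement patterns (% of users):")
for pattern, pct in shares.items():
    print(f"  {pattern:22s} {pct:5.1f}")
ratio = single_message_rate_ratio(records, corpus.users)
print(f"men {ratio:.2f}x as likely as women to send exactly one message and get one reply")

vol = weekly_volume(corpus).table
print(f"\nweekly volume spans {len(vol)} ISO weeks; busiest week: "
      f"{vol.loc[vol.n_inbound.idxmax(), ['iso_year', 'iso_week', 'n_inbound']].tolist()}")
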
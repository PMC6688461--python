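"""Detect message language, impute weekly labels, measure discordance.

The character n-gram naive Bayes model separates English from Swahili and
returns `und` for unreliable text (digits, emoticons, too-short strings);
`und` labels are then filled from the user's weekly dominant language.
"""

from chatmine import resources
from chatmine.langid import (
    detect_corpus,
    detect_language,
    discordance,
    impute_weekly_language,
    language_mix,
)
from chatmine.synthetic import GeneratorConfig, generate_corpus

model = resources.default_language_model()
for text in [
    "what is the best method of family planning",
    "nataka kujua kuhusu uzazi wa mpango",
    "0712345678",
]:
    label, margin = detect_language(model, text)
    print(f"{label:4s} (margin {margin:6.3f})  {text!r}")

corpus, _ = generate_corpus(GeneratorConfig(n_users=1500, seed=7))
detect_corpus(corpus, model)
pre = language_mix(corpus)
impute_weekly_language(corpus)
post = language_mix(corpus)
print(f"\nbefore imputation: en {pre['en']:.1f}% / sw {pre['sw']:.1f}% / und {pre['und']:.1f}%")
print(f"after  imputation: en {post['en']:.1f}% / sw {post['sw']:.1f}% / und {post['und']:.1f}%")

rep = discordance(corpus)
print(f"\n{rep.pct_messages_discordant:.1f}% of labeled inbound messages mismatch the "
      f"sender's stated preference; {rep.pct_users_any_discordant:.1f}% of users "
      f"have at least one such message")
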
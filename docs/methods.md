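# Methods

This note documents the models, parameter choices and design decisions
behind the package, and what the synthetic-data tests do and do not show
about real chat corpora.

## Language identification

The classifier is a naive Bayes over character n-grams (default n = 2–4)
with additive smoothing α = 0.5 and uniform priors.  Text is lowercased and
reduced to letter runs before n-gram extraction, so digits and punctuation
never contribute evidence.  The decision statistic is the per-character mean
log-likelihood margin between the best and second-best language; results
below a reliability threshold (default 0.05 per character) are returned as
`und`.  The threshold default was chosen so that near-random character
strings — which score almost equally under both models — fall below it,
while genuinely in-language text of a few words clears it by an order of
magnitude (the packaged model's margins on in-language sentences are
typically 3–7 per character).  Priors are uniform deliberately: in a
code-switching corpus the training mix carries no information about the
deployment mix.

The packaged default model is trained on two synthetic seed texts (one per
language, ~2.5 kB each) written for this package in the health-information
register the pipeline targets.  They are compositions, not excerpts of any
chat corpus.  Any external detector can be substituted wherever a
`detect(text) -> (label, score)` callable is accepted.

**Weekly imputation.**  An `und` inbound message takes the modal non-`und`
label among the same user's inbound messages of the same ISO-8601 week.
ISO weeks are used because they are unambiguous across year boundaries.  A
weekly tie falls back to the user's overall dominant detected language;
a second tie leaves `und`.  The rule never changes a non-`und` label and
never touches outbound messages, so it is idempotent.

## Normalization

Pipeline order is fixed and documented: tokenize → spell-correct →
lemmatize → collapse synonyms → bigram preemption → stop-word filter.
Order changes counts, and descriptions of such pipelines are often
ambiguous about it, so the order is part of the contract here.  Tokens are
maximal Unicode letter runs; apostrophes are removed with the halves joined
("don't" → "dont"); an alphanumeric mode keeps digit-bearing tokens such as
brand names ("p2").  Standalone numbers are dropped by default.

Spell correction is deliberately conservative: a suggestion is accepted
only for tokens rarer than 4 occurrences in the corpus (rare tokens are
overwhelmingly typos; frequent ones are domain vocabulary a generic
dictionary would "correct" wrongly), and only for English — Swahili tokens
are never corrected, because no reliable Swahili suggestion source is
assumed.  The suggester interface is pluggable; the shipped default offers
alphabetically-first edit-distance-1 matches against a packaged English
wordlist and proposes nothing for in-vocabulary tokens.

Lemmatization is table lookup (no suffix stripping, so no non-word stems);
the loader rejects non-idempotent tables.  Synonym maps reject chains and
cycles at load, which makes application idempotent by construction.  Stop
lists ship in a `word,language,source` CSV dialect: a frozen copy of
scikit-learn's public 318-word English list, a custom chat-register English
addition list, and an 80-word Swahili function-word list.  Stop lists are
configuration, not constants — counts of stop words are lexicon-version
artifacts.

## Frequency and associations

Bigram preemption is a greedy left-to-right, non-overlapping scan: when the
pair at the cursor is a key bigram, the bigram is emitted and both tokens
are consumed; otherwise the single token is emitted.  Greedy scanning
matches the natural reading of "tally the word as part of its pair when the
pair occurs" and is deterministic; the test suite checks it against an
oracle that enumerates all tilings of random streams.  Token conservation
(singles + 2·bigrams = stream length) holds for every message.  Pairing
runs before stop-word filtering of singles so adjacency is judged on the
full normalized stream; key bigrams themselves may not contain stop words.

Default age bands are 15–19, 20–24, 25–35 and 36+ (configurable).  Forced
ranks break ties lexicographically so every rank 1..N is used exactly once.

Phi is computed from the 2×2 presence table over sections and equals the
Pearson correlation of the binary indicators (property-tested to 1e-12).
The default section unit is the user — all of one user's inbound messages
of one language pooled — because co-occurrence questions here are about
what a person talks about, not about single-message adjacency.  Terms in
fewer than 20 sections are excluded by default (phi is unstable for rare
terms), and zero-denominator pairs (terms present in all or no sections)
are omitted rather than assigned 0.  Both knobs are exposed.

## Engagement and conversations

The five-class engagement partition is a pure function of the per-user
(inbound, outbound) counts.  Three classes dominate real corpora of this
kind; the remaining two (single-in/multi-out and no-reply) are reported
explicitly rather than folded away, so shares provably sum to 100%.

Conversations are segmented by an inactivity gap (default 24 h): a
reproducible proxy for the manual delimitation a human coder would apply.
Counts from the gap rule approximate, not reproduce, manual coding.
Decreasing the gap threshold never merges conversations (monotonicity is
property-tested).  Topic labels, message codes, question categories
(1 factual-causes, 2 factual-concepts, 3 advice, 4 access, 5 symptoms,
6 other) and myth flags are rater-produced input data; the module defines
their schema and aggregations only.  A seeded sampler selects
high-engagement users (≥ 7 same-week messages in one language, balanced by
sex) for coding exercises.

## Intent adjudication

The final label of a question is the first label independently given by two
distinct raters, resolved at the earliest presentation index where such a
pair exists; the same rater repeating a label never counts.  Duplicate
presentation indices are integrity errors, which also rules out the
otherwise-possible tie of two labels reaching agreement simultaneously.
Marketing flags per intent are input data.

## Synthetic generator

The generator's defaults are the study conditions the pipeline assumes:

* **Demographics:** 63.2% female (44.7% missing), 46.7% English preference
  (1.1% missing), age truncated-normal on [15, 65] with *truncated* mean
  22.5 and SD 6.4 years (49.3% missing).  The underlying normal location
  and scale are solved numerically so the realized moments match the
  targets instead of drifting upward from truncation.
* **Message volume:** per-user inbound count X = 1 + NB(mean − 1, r) with
  mean 3.1 and r = 0.55, giving median 2 and SD ≈ 3.3.  Matching a mean of
  3.1 *and* an SD of 4.3 would force r ≈ 0.27 and push the median to 1, so
  the generator privileges the median/mean pair; the tail is therefore
  somewhat lighter than in the heaviest real corpora.
* **Languages:** English-preferring users send 1.71× more messages than
  Swahili-preferring users, and per-message language is drawn conditional
  on preference — (0.8825, 0.0875, 0.03) given English preference,
  (0.219, 0.751, 0.03) given Swahili.  Jointly these yield a ~63.6%
  English share among labeled messages and ~14.4% message-level
  discordance; without the volume asymmetry those two quantities are
  mutually inconsistent with a 46.7% preference share.  `und` messages are
  realized as digit strings, so the detector genuinely fails on them
  rather than being told the answer.  Because code-switching is iid per
  message, *user-level* discordance (any mismatched message) comes out
  near 30%; correlated switching in real corpora concentrates mismatches
  in fewer users.
* **Engagement:** reply behavior is drawn conditional on single vs multiple
  inbound messages — (0.911, 0.068, 0.021) and (0.160, 0.820, 0.020) over
  (one reply, multiple replies, none) — and the one-message probability is
  scaled by sex so that men are 1.7× likelier than women to be
  one-in/one-out users, mean-preservingly.
* **Content:** bodies are bags of 1–2 phrases from weighted cohort lexicons
  (sex × age band for English; a shared Swahili pool); each cohort carries
  signature vocabulary, including a planted term ("prostate") exclusive to
  the oldest-male cohort that the stratified forced rank must place first
  there and nowhere else.  2% of English messages get a random
  single-letter deletion so the spell policy has real work.
* **Coded conversations:** generated directly at the coded-subset
  conditions — 100 users balanced by sex, conversations per person
  1 + NB(1.1, 0.55) (mean 2.1, median 1), messages per conversation
  2 + NB(10.5, 1.61) (mean 12.5, SD ≈ 8.9), topics per conversation
  1 + NB(1.6, 1.0) (mean 2.6, ~62% multi-topic), 72% of user messages
  questions with category shares (48.9, 11.2, 26.0, 1.5, 10.6, 1.8)% and a
  4.7% myth rate among information requests.
* **Label events:** each presentation gives the true intent with
  probability 1 − 0.3, otherwise a rater-specific wrong label chosen so no
  two raters can share a wrong label on a question; double agreement is
  therefore only ever reached on the truth, which is what makes the
  end-to-end adjudication test exact.

Generation is fully reproducible under a fixed seed (a single
`numpy` generator drives everything).

**What passing tests show — and don't.**  Parameter recovery on this
generator demonstrates that every pipeline stage measures what it claims on
data with the assumed structure: correct detection and imputation, exact
tallying and ranking, unbiased share estimation within 99% intervals at
10,000 users.  It does not demonstrate robustness to what the generator
lacks: real orthographic variety and slang, grammatical text (phi values
between within-phrase word pairs are near 1 by construction here),
correlated code-switching, topic drift over time, or the messiness of real
timestamps.  Statistical recovery checks use the user count as the
effective sample size for message-level shares, because messages cluster
within users.

## Numerical and edge-case choices

Empty corpora, all-stop-word streams, unknown strata, zero-denominator phi
pairs, undefined discordance (no known preferences) and undefined sex
ratios (zero female share) all have explicit, tested behaviors — errors
where the quantity is meaningless, flagged/omitted values where it is
merely undefined.  Ranking and bigram-discovery ties break
lexicographically everywhere, so all outputs are deterministic.  Problem
sizes in the test suite (up to 10,000 users, ~31,000 inbound messages) were
chosen as the smallest at which the 99%-interval recovery checks have
comfortable margins.
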
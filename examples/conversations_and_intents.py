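"""Conversation analytics and double-agreement intent adjudication.

Conversations are inactivity-gap segments (default 24 h).  Coded topics,
message codes and question categories are rater-produced input data; the
module aggregates them.  Intent labels resolve when two distinct raters
agree.
"""

from datetime import timedelta

from chatmine.conversations import (
    conversation_stats,
    question_distribution,
    segment_corpus,
    topic_cooccurrence,
)
from chatmine.intents import events_from_frame, intent_distribution, resolve_all
from chatmine.synthetic import (
    MARKETED_INTENTS,
    GeneratorConfig,
    generate_coded_conversations,
    generate_corpus,
    generate_label_events,
    make_questions,
)

config = GeneratorConfig(n_users=2000, seed=5)
corpus, _ = generate_corpus(config)

convs = segment_corpus(corpus, timedelta(hours=24))
print(f"{len(convs)} conversations across {len(corpus.users)} users")

conversations, coded, topics, coded_users = generate_coded_conversations(config)
stats = conversation_stats(conversations, topics, coded_users)
print("\ncoded-conversation characteristics:")
print(stats[["group", "n_users", "n_conversations", "convos_per_person_mean",
             "messages_per_convo_mean", "topics_per_convo_mean"]].head(3).to_string(index=False))

dist = question_distribution(coded)
print(f"\n{dist.n_questions} questions; shares by category (%):",
      {k: round(v, 1) for k, v in dist.pct_by_category.items()})
print(f"myth questions among {dist.n_information_requests} information requests: "
      f"{dist.pct_myth_among_information:.1f}%")
print("top co-occurring topic pairs:")
print(topic_cooccurrence(topics).head(5).to_string(index=False))

questions = make_questions(corpus, config)
events = generate_label_events(config, questions)
res = resolve_all(events_from_frame(events))
idist = intent_distribution(
    res, dict(zip(questions.question_id, questions.user_id)), corpus.users, MARKETED_INTENTS
)
print(f"\n{idist.n_resolved} questions resolved ({idist.n_unresolved} unresolved); top intents:")
print(idist.overall.sort_values('n', ascending=False).head(5).to_string(index=False))
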
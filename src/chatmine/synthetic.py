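"""Synthetic two-way chat corpus generator with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a mostly-female, young user base; stated language preference with
per-message code-switching; heavy-tailed per-user message counts; agent
replies realizing a configured engagement-pattern mix; undetectable
(digits-only) messages; cohort-specific topic vocabularies with planted
signature terms; occasional misspellings; plus label-event logs for the
double-agreement protocol and coded-conversation tables.

Message bodies are bags of phrases drawn from per-cohort lexicons — no
grammar.  That is sufficient for every statistic the pipeline computes
(token frequencies, adjacency, co-occurrence, language identity) while
keeping the generator inspectable.

Distribution choices, with defaults mirroring the study population:

* per-user inbound count: shifted negative binomial ``1 + NB(mean-1, r)``
  with ``r = 0.55``, giving median 2 and mean 3.1;
* age: normal truncated to [15, 65] whose *truncated* mean/SD are solved
  numerically to hit the configured 22.5 / 6.4;
* English-preferring users send ``english_pref_volume_factor`` (1.71) times
  more messages than Swahili-preferring users, which is what makes a 46.7%
  English preference share coexist with a ~63% English message share and
  ~14% message-level discordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .corpus import Corpus, Message, UserRecord
from .errors import ParameterError

SPAN_START = datetime(2017, 9, 18, tzinfo=timezone.utc)
SPAN_END = datetime(2019, 1, 28, tzinfo=timezone.utc)

# ---------------------------------------------------------------------------
# Lexicons.  Weighted phrase pools per cohort; weights are relative draws.

BASE_EN: list[tuple[str, float]] = [
    ("what is family planning", 3.0),
    ("best method of family planning", 3.0),
    ("side effects of family planning", 2.5),
    ("family planning methods", 2.0),
    ("i want to prevent pregnancy", 2.0),
    ("morning after pill", 1.5),
    ("emergency pill after unprotected sex", 1.5),
    ("how effective are condoms", 1.5),
    ("implant side effects", 1.5),
    ("injection side effects", 1.5),
    ("can i get pregnant during my period", 1.5),
    ("my period is late am i pregnant", 1.5),
    ("irregular periods", 1.0),
    ("how to use birth control pills", 1.0),
    ("hiv test near me", 1.0),
    ("sti symptoms", 1.0),
    ("heavy bleeding during period", 0.8),
    ("abdominal pains during periods", 0.8),
]

SIGNATURE_EN: dict[tuple[str, str], list[tuple[str, float]]] = {
    ("male", "15-19"): [
        ("unprotected sex", 6.0),
        ("safe sex", 3.0),
        ("can she get pregnant", 3.0),
        ("oral sex", 1.5),
    ],
    ("male", "20-24"): [
        ("unprotected sex", 5.0),
        ("safe sex", 3.0),
        ("sex during pregnancy", 1.5),
        ("prevent hiv", 1.5),
    ],
    ("male", "25-35"): [
        ("unprotected sex", 4.0),
        ("safe sex", 3.0),
        ("low libido", 1.5),
        ("prevent hiv", 1.5),
    ],
    ("male", "36+"): [
        ("prostate", 30.0),
        ("cancer screening for men", 3.0),
        ("sex", 2.0),
    ],
    ("female", "15-19"): [
        ("safe days", 6.0),
        ("unsafe days", 4.0),
        ("period pains", 3.0),
        ("pregnancy test", 2.0),
    ],
    ("female", "20-24"): [
        ("safe days", 4.0),
        ("period pains", 3.0),
        ("pregnancy test", 2.0),
        ("which contraception is best", 2.0),
    ],
    ("female", "25-35"): [
        ("family planning after birth", 4.0),
        ("conceive after implant", 2.5),
        ("period pains", 2.0),
        ("breastfeeding and pregnancy", 1.5),
    ],
    ("female", "36+"): [
        ("breast cancer", 5.0),
        ("cervical cancer screening", 4.0),
        ("conceive at my age", 2.0),
        ("family planning", 2.0),
    ],
}

BASE_SW: list[tuple[str, float]] = [
    ("nataka kujua kuhusu uzazi wa mpango", 3.0),
    ("njia bora ya kuzuia mimba", 3.0),
    ("madhara ya sindano ni yapi", 2.0),
    ("madhara ya vidonge vya uzazi", 2.0),
    ("siku salama ni zipi", 2.0),
    ("je naweza kupata mimba siku za hedhi", 1.5),
    ("hedhi yangu imechelewa", 1.5),
    ("vidonge vya dharura", 1.5),
    ("kitanzi kina madhara gani", 1.0),
    ("dalili za ugonjwa wa zinaa", 1.0),
    ("kupima virusi vya ukimwi", 1.0),
    ("maumivu wakati wa hedhi", 1.0),
]

AGENT_REPLIES: list[str] = [
    "thank you for your question",
    "the best method depends on your body and your plans",
    "please visit your nearest clinic for personal advice",
    "condoms protect against both pregnancy and infections",
    "you can take the emergency pill within three days",
    "side effects usually settle after a few months",
    "a nurse will answer your question shortly",
    "karibu tafadhali uliza swali lako",
]

#: Default intent taxonomy with marketing flags (input data in the field).
INTENTS: list[str] = [
    "find contraception method",
    "contraception side effects",
    "emergency contraception",
    "pregnancy question",
    "menstruation question",
    "sti question",
    "hiv question",
    "sexual health",
    "relationships",
    "symptom report",
    "access to services",
    "other",
]
MARKETED_INTENTS: dict[str, bool] = {
    intent: intent
    in {
        "find contraception method",
        "contraception side effects",
        "emergency contraception",
    }
    for intent in INTENTS
}
INTENT_PROBS: tuple[float, ...] = (
    0.28, 0.12, 0.08, 0.10, 0.08, 0.08, 0.06, 0.07, 0.05, 0.04, 0.02, 0.02,
)

TOPICS: list[tuple[str, float]] = [
    ("contraception", 8.0),
    ("fertility", 5.0),
    ("sti", 4.0),
    ("relationships", 3.5),
    ("sex pains", 3.0),
    ("unsafe days", 3.0),
    ("menstruation", 3.0),
    ("emergency contraception", 2.5),
    ("hiv", 2.0),
    ("pregnancy", 2.0),
    ("condoms", 1.5),
    ("implant", 1.5),
    ("injection", 1.2),
    ("pills", 1.2),
    ("cancer", 1.0),
    ("body changes", 1.0),
    ("services", 0.8),
    ("myths", 0.8),
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All the dials of the synthetic corpus, with study-condition defaults."""

    n_users: int = 1000
    seed: int = 0
    # demographics
    female_share: float = 0.632
    sex_missing: float = 0.447
    age_mean: float = 22.5
    age_sd: float = 6.4
    age_range: tuple[float, float] = (15.0, 65.0)
    age_missing: float = 0.493
    english_pref_share: float = 0.467
    pref_missing: float = 0.011
    # message volume: X = 1 + NB(mean-1, dispersion), median 2 / mean 3.1
    messages_per_user_mean: float = 3.1
    messages_per_user_dispersion: float = 0.55
    english_pref_volume_factor: float = 1.71
    # per-message language conditional on preference: (en, sw, und)
    language_mix_given_en_pref: tuple[float, float, float] = (0.8825, 0.0875, 0.03)
    language_mix_given_sw_pref: tuple[float, float, float] = (0.219, 0.751, 0.03)
    # engagement: men this much likelier than women to be one-message users
    single_message_sex_ratio: float = 1.7
    # reply pattern conditional on single vs multiple inbound messages
    reply_given_single: tuple[float, float, float] = (0.911, 0.068, 0.021)
    reply_given_multi: tuple[float, float, float] = (0.160, 0.820, 0.020)
    misspell_prob: float = 0.02
    n_agents: int = 18
    # conversation structure: convos per user = 1 + NB(conv_mean-1, conv_disp)
    convos_per_person_mean: float = 2.1
    convos_per_person_dispersion: float = 0.55
    # coded-conversation generator (high-engagement subset conditions)
    coded_n_users: int = 100
    coded_messages_per_convo_mean: float = 12.5
    coded_messages_per_convo_dispersion: float = 1.61
    coded_user_message_share: float = 0.528
    coded_topics_per_convo_mean: float = 2.6
    coded_topics_per_convo_dispersion: float = 1.0
    question_share: float = 0.72
    category_probs: tuple[float, ...] = (0.489, 0.112, 0.260, 0.015, 0.106, 0.018)
    myth_prob: float = 0.047
    # intent labeling
    n_raters: int = 8
    disagreement_rate: float = 0.3
    planted_terms: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"prostate": ("male", "36+")}
    )

    def validate(self) -> None:
        problems = []
        if self.n_users < 1:
            problems.append("n_users must be >= 1")
        for name in (
            "female_share",
            "sex_missing",
            "age_missing",
            "english_pref_share",
            "pref_missing",
            "misspell_prob",
            "question_share",
            "myth_prob",
            "disagreement_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        for name in (
            "language_mix_given_en_pref",
            "language_mix_given_sw_pref",
            "reply_given_single",
            "reply_given_multi",
            "category_probs",
        ):
            v = getattr(self, name)
            if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-6:
                problems.append(f"{name}={v} is not a probability distribution")
        if self.messages_per_user_mean <= 1.0:
            problems.append("messages_per_user_mean must exceed 1")
        if self.messages_per_user_dispersion <= 0:
            problems.append("messages_per_user_dispersion must be positive")
        if self.english_pref_volume_factor <= 0:
            problems.append("english_pref_volume_factor must be positive")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass
class GroundTruth:
    """Realized truth aligned row-for-row with the emitted corpus."""

    users: pd.DataFrame  # user_id, sex, age, language_preference
    messages: pd.DataFrame  # message_id, user_id, true_language
    patterns: pd.DataFrame  # user_id, n_inbound, n_outbound, pattern
    intents: pd.DataFrame | None = None  # question_id, user_id, true_intent


# ---------------------------------------------------------------------------
# Distribution helpers


@lru_cache(maxsize=None)
def _truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying normal (loc, scale) whose [lo, hi]-truncation has the
    requested mean and SD."""

    def moments(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    loc, scale = optimize.fsolve(moments, x0=[mean, sd], full_output=False)
    return float(loc), float(abs(scale))


def _group_nb_params(cfg: GeneratorConfig) -> dict[str, tuple[float, float]]:
    """Shifted-NB (mu, p) per preference group, volume factor applied."""
    k = cfg.english_pref_volume_factor
    w = cfg.english_pref_share
    m_sw = cfg.messages_per_user_mean / (w * k + (1 - w))
    means = {"en": k * m_sw, "sw": m_sw}
    r = cfg.messages_per_user_dispersion
    out = {}
    for g, m in means.items():
        mu = m - 1.0  # NB part of X = 1 + NB
        out[g] = (mu, r / (r + mu))
    return out


def _sample_shifted_nb(rng, mu: float, r: float, size: int) -> np.ndarray:
    p = r / (r + mu)
    return 1 + rng.negative_binomial(r, p, size=size)


def _weighted_choice(rng, items: Sequence[tuple[str, float]]) -> str:
    weights = np.array([w for _, w in items], dtype=float)
    idx = rng.choice(len(items), p=weights / weights.sum())
    return items[idx][0]


def _age_band(age: float) -> str:
    if age <= 19:
        return "15-19"
    if age <= 24:
        return "20-24"
    if age <= 35:
        return "25-35"
    return "36+"


def _misspell(rng, phrase: str) -> str:
    words = phrase.split()
    candidates = [i for i, w in enumerate(words) if len(w) >= 5]
    if not candidates:
        return phrase
    i = int(rng.choice(candidates))
    w = words[i]
    drop = int(rng.integers(1, len(w) - 1))
    words[i] = w[:drop] + w[drop + 1 :]
    return " ".join(words)


def _en_body(rng, sex: str, band: str, misspell_prob: float) -> str:
    lexicon = BASE_EN + SIGNATURE_EN.get((sex, band), [])
    n_phrases = 1 + int(rng.random() < 0.5)
    phrases = [_weighted_choice(rng, lexicon) for _ in range(n_phrases)]
    body = " ".join(phrases)
    if rng.random() < misspell_prob:
        body = _misspell(rng, body)
    return body


def _sw_body(rng) -> str:
    n_phrases = 1 + int(rng.random() < 0.4)
    return " ".join(_weighted_choice(rng, BASE_SW) for _ in range(n_phrases))


def _und_body(rng) -> str:
    return "07" + "".join(str(d) for d in rng.integers(0, 10, size=8))


# ---------------------------------------------------------------------------
# Corpus generation


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus aligned ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nb = _group_nb_params(config)
    loc, scale = _truncnorm_params(
        config.age_mean, config.age_sd, *config.age_range
    )
    a = (config.age_range[0] - loc) / scale
    b = (config.age_range[1] - loc) / scale

    n = config.n_users
    sexes = np.where(rng.random(n) < config.female_share, "female", "male")
    ages = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    prefs = np.where(rng.random(n) < config.english_pref_share, "en", "sw")

    # sex-specific adjustment of the one-message probability, mean-preserving
    fs = config.female_share
    ratio = config.single_message_sex_ratio
    c_female = 1.0 / (fs + ratio * (1 - fs))
    c_male = ratio * c_female

    span_seconds = (SPAN_END - SPAN_START).total_seconds()
    messages: list[Message] = []
    users: dict[str, UserRecord] = {}
    truth_users = []
    truth_msgs = []
    truth_patterns = []
    mid = 0

    for i in range(n):
        uid = f"u{i:05d}"
        sex, age, pref = str(sexes[i]), float(ages[i]), str(prefs[i])
        band = _age_band(age)
        mu, p = nb[pref]
        p1 = float(stats.nbinom.pmf(0, config.messages_per_user_dispersion, p))
        q_single = min(1.0, p1 * (c_male if sex == "male" else c_female))
        if rng.random() < q_single:
            n_in = 1
        else:
            # draw from 1 + NB conditioned on NB >= 1 via inverse CDF
            u = rng.uniform(p1, 1.0)
            n_in = 1 + int(
                stats.nbinom.ppf(u, config.messages_per_user_dispersion, p)
            )
            n_in = max(n_in, 2)

        reply_probs = (
            config.reply_given_single if n_in == 1 else config.reply_given_multi
        )
        reply_kind = ("single_out", "multi_out", "none")[
            int(rng.choice(3, p=reply_probs))
        ]
        if reply_kind == "none":
            n_out = 0
        elif reply_kind == "single_out":
            n_out = 1
        else:
            n_out = max(2, int(rng.poisson(max(n_in * 1.05, 2.2))))

        # conversation bursts: gaps > 24 h between, minutes within
        k_conv = min(
            n_in,
            int(
                _sample_shifted_nb(
                    rng,
                    config.convos_per_person_mean - 1.0,
                    config.convos_per_person_dispersion,
                    1,
                )[0]
            ),
        )
        sizes = np.ones(k_conv, dtype=int)
        for _ in range(n_in - k_conv):
            sizes[int(rng.integers(k_conv))] += 1

        anchor = SPAN_START + timedelta(
            seconds=float(rng.uniform(0, span_seconds - 14 * 86400))
        )
        inbound_times: list[datetime] = []
        t = anchor
        for size in sizes:
            for j in range(int(size)):
                if j > 0:
                    t += timedelta(minutes=float(rng.uniform(2, 30)))
                inbound_times.append(t)
            t += timedelta(hours=30.0 + float(rng.exponential(36.0)))

        langs = rng.choice(
            ["en", "sw", "und"],
            size=n_in,
            p=(
                config.language_mix_given_en_pref
                if pref == "en"
                else config.language_mix_given_sw_pref
            ),
        )
        for j in range(n_in):
            lang = str(langs[j])
            if lang == "en":
                body = _en_body(rng, sex, band, config.misspell_prob)
            elif lang == "sw":
                body = _sw_body(rng)
            else:
                body = _und_body(rng)
            mid += 1
            messages.append(
                Message(
                    message_id=f"m{mid:07d}",
                    user_id=uid,
                    direction="inbound",
                    timestamp=inbound_times[j],
                    body=body,
                )
            )
            truth_msgs.append((f"m{mid:07d}", uid, lang))

        for j in range(n_out):
            anchor_in = inbound_times[min(j, n_in - 1)]
            ts = anchor_in + timedelta(
                minutes=float(rng.uniform(1, 10)) + 10.0 * (j // max(n_in, 1))
            )
            mid += 1
            messages.append(
                Message(
                    message_id=f"m{mid:07d}",
                    user_id=uid,
                    direction="outbound",
                    timestamp=ts,
                    body=str(
                        AGENT_REPLIES[int(rng.integers(len(AGENT_REPLIES)))]
                    ),
                    agent_id=f"a{1 + int(rng.integers(config.n_agents)):02d}",
                )
            )

        obs_sex = "unknown" if rng.random() < config.sex_missing else sex
        obs_age = None if rng.random() < config.age_missing else round(age)
        obs_pref = "unknown" if rng.random() < config.pref_missing else pref
        users[uid] = UserRecord(
            user_id=uid,
            sex=obs_sex,
            age_years=obs_age,
            language_preference=obs_pref,
        )
        truth_users.append((uid, sex, age, pref))
        if n_out == 0:
            pattern = "no_reply"
        elif n_in == 1:
            pattern = "single_in_single_out" if n_out == 1 else "single_in_multi_out"
        else:
            pattern = "multi_in_single_out" if n_out == 1 else "multi_in_multi_out"
        truth_patterns.append((uid, n_in, n_out, pattern))

    corpus = Corpus(messages=messages, users=users)
    truth = GroundTruth(
        users=pd.DataFrame(
            truth_users, columns=["user_id", "sex", "age", "language_preference"]
        ),
        messages=pd.DataFrame(
            truth_msgs, columns=["message_id", "user_id", "true_language"]
        ),
        patterns=pd.DataFrame(
            truth_patterns, columns=["user_id", "n_inbound", "n_outbound", "pattern"]
        ),
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# Label events


def make_questions(
    corpus: Corpus, config: GeneratorConfig, n_questions: int | None = None
) -> pd.DataFrame:
    """First inbound message per user as the intent-classification question
    pool, with a true intent drawn per question."""
    rng = np.random.default_rng(config.seed + 1)
    firsts: dict[str, Message] = {}
    for m in corpus.inbound():
        cur = firsts.get(m.user_id)
        if cur is None or (m.timestamp, m.message_id) < (cur.timestamp, cur.message_id):
            firsts[m.user_id] = m
    rows = [(m.message_id, uid) for uid, m in sorted(firsts.items())]
    if n_questions is not None:
        rows = rows[:n_questions]
    intents = rng.choice(INTENTS, size=len(rows), p=INTENT_PROBS)
    return pd.DataFrame(
        [(qid, uid, str(intent)) for (qid, uid), intent in zip(rows, intents)],
        columns=["question_id", "user_id", "true_intent"],
    )


def generate_label_events(
    config: GeneratorConfig, questions: pd.DataFrame
) -> pd.DataFrame:
    """Simulate the labeling queue under a configurable disagreement rate.

    Each presentation, the rater gives the true intent with probability
    ``1 - disagreement_rate`` and otherwise a *rater-specific* wrong label,
    so two distinct raters can only ever agree on the truth: every resolved
    question resolves to its true intent by construction.  Questions are
    withdrawn unresolved once every rater has seen them.
    """
    if len(INTENTS) <= config.n_raters:
        raise ParameterError("need more intent labels than raters")
    rng = np.random.default_rng(config.seed + 2)
    label_index = {lab: i for i, lab in enumerate(INTENTS)}
    rows = []
    for q in questions.itertuples():
        rater_order = rng.permutation(config.n_raters)
        counts: dict[str, set[int]] = {}
        for seq, rater in enumerate(rater_order, start=1):
            rater = int(rater)
            if rng.random() < config.disagreement_rate:
                t = label_index[q.true_intent]
                wrong = INTENTS[(t + 1 + rater) % len(INTENTS)]
                label = wrong if wrong != q.true_intent else INTENTS[(t + 2) % len(INTENTS)]
            else:
                label = q.true_intent
            rows.append((q.question_id, f"r{rater:02d}", label, seq))
            prior = counts.setdefault(label, set())
            if any(r != rater for r in prior):
                break
            prior.add(rater)
    return pd.DataFrame(
        rows, columns=["question_id", "rater_id", "label", "sequence_index"]
    )


# ---------------------------------------------------------------------------
# Coded conversations (high-engagement subset conditions)


def generate_coded_conversations(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, UserRecord]]:
    """Generate a coded-conversation table set.

    Returns (conversations, coded_messages, topics, users): the schema the
    conversation-analytics operations aggregate, with the configured
    per-conversation message counts, topic counts, question share, category
    distribution and myth rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    n_users = config.coded_n_users
    users: dict[str, UserRecord] = {}
    conv_rows = []
    msg_rows = []
    topic_rows = []
    topic_labels = [t for t, _ in TOPICS]
    topic_weights = np.array([w for _, w in TOPICS])
    topic_weights = topic_weights / topic_weights.sum()

    for i in range(n_users):
        uid = f"c{i:03d}"
        sex = "female" if i < n_users // 2 else "male"
        age = float(np.clip(rng.normal(21.4, 3.7), 15, 35))
        users[uid] = UserRecord(uid, sex=sex, age_years=round(age), language_preference="en")
        k_conv = int(
            _sample_shifted_nb(
                rng,
                config.convos_per_person_mean - 1.0,
                config.convos_per_person_dispersion,
                1,
            )[0]
        )
        for c in range(k_conv):
            cid = f"{uid}-c{c + 1}"
            mu = config.coded_messages_per_convo_mean - 2.0
            r = config.coded_messages_per_convo_dispersion
            n_msgs = 2 + int(rng.negative_binomial(r, r / (r + mu)))
            n_user = int(np.clip(rng.binomial(n_msgs, config.coded_user_message_share), 1, n_msgs - 1))
            conv_rows.append((cid, uid, n_user, n_msgs - n_user, n_msgs))
            n_topics = int(
                _sample_shifted_nb(
                    rng,
                    config.coded_topics_per_convo_mean - 1.0,
                    config.coded_topics_per_convo_dispersion,
                    1,
                )[0]
            )
            n_topics = min(n_topics, len(topic_labels))
            chosen = rng.choice(
                len(topic_labels), size=n_topics, replace=False, p=topic_weights
            )
            for t in chosen:
                topic_rows.append((cid, topic_labels[int(t)]))
            for j in range(n_user):
                if rng.random() < config.question_share:
                    cat = 1 + int(rng.choice(6, p=config.category_probs))
                    myth = bool(rng.random() < config.myth_prob) if cat in (1, 2) else False
                    msg_rows.append((cid, uid, "question_request", cat, myth))
                else:
                    code = ("response", "greeting", "other")[int(rng.choice(3, p=[0.6, 0.3, 0.1]))]
                    msg_rows.append((cid, uid, code, None, False))

    conversations = pd.DataFrame(
        conv_rows,
        columns=["conversation_id", "user_id", "n_user_messages", "n_agent_messages", "n_messages"],
    )
    coded_messages = pd.DataFrame(
        msg_rows, columns=["conversation_id", "user_id", "code", "category", "myth"]
    )
    topics = pd.DataFrame(topic_rows, columns=["conversation_id", "topic"])
    return conversations, coded_messages, topics, users


# ---------------------------------------------------------------------------
# Analytic expectations (for recovery comparisons)


def expected_language_marginal(config: GeneratorConfig) -> tuple[float, float, float]:
    """Message-weighted (en, sw, und) marginal implied by the config."""
    k = config.english_pref_volume_factor
    w = config.english_pref_share
    m_sw = config.messages_per_user_mean / (w * k + (1 - w))
    s = w * k * m_sw / config.messages_per_user_mean
    en = s * config.language_mix_given_en_pref[0] + (1 - s) * config.language_mix_given_sw_pref[0]
    sw = s * config.language_mix_given_en_pref[1] + (1 - s) * config.language_mix_given_sw_pref[1]
    und = 1.0 - en - sw
    return (en, sw, und)


def expected_discordance(config: GeneratorConfig) -> float:
    """Expected message-level discordance among labeled messages."""
    k = config.english_pref_volume_factor
    w = config.english_pref_share
    m_sw = config.messages_per_user_mean / (w * k + (1 - w))
    s = w * k * m_sw / config.messages_per_user_mean
    disc = (
        s * config.language_mix_given_en_pref[1]
        + (1 - s) * config.language_mix_given_sw_pref[0]
    )
    en, sw, _ = expected_language_marginal(config)
    return disc / (en + sw)


def expected_single_share(config: GeneratorConfig) -> float:
    """Probability a user sends exactly one inbound message."""
    r = config.messages_per_user_dispersion
    total = 0.0
    for pref, weight in (("en", config.english_pref_share), ("sw", 1 - config.english_pref_share)):
        mu, p = _group_nb_params(config)[pref]
        total += weight * float(stats.nbinom.pmf(0, r, p))
    return total


def expected_engagement_shares(config: GeneratorConfig) -> dict[str, float]:
    p1 = expected_single_share(config)
    s = config.reply_given_single
    m = config.reply_given_multi
    return {
        "single_in_single_out": p1 * s[0],
        "single_in_multi_out": p1 * s[1],
        "multi_in_single_out": (1 - p1) * m[0],
        "multi_in_multi_out": (1 - p1) * m[1],
        "no_reply": p1 * s[2] + (1 - p1) * m[2],
    }


# ---------------------------------------------------------------------------
# Recovery report


def _binomial_ci(p: float, n: int, z: float = 2.5758) -> float:
    return z * np.sqrt(max(p * (1 - p), 1e-12) / n)


def recovery_report(
    config: GeneratorConfig,
    recovered: Mapping[str, float],
    ns: Mapping[str, int],
) -> pd.DataFrame:
    """Configured-vs-recovered comparison with 99% intervals.

    ``recovered`` maps quantity names to pipeline measurements (shares as
    proportions in [0, 1], means in natural units); ``ns`` gives the sample
    size behind each.  Quantities understood: female_share, age_mean,
    age_sd, english_pref_share, english_share_labeled, discordance,
    engagement pattern shares, single_message_sex_ratio, planted-term ranks
    (``planted_rank:<term>``).
    """
    z = 2.5758  # 99% two-sided normal quantile
    eng = expected_engagement_shares(config)
    en, sw, _ = expected_language_marginal(config)
    configured: dict[str, float] = {
        "female_share": config.female_share,
        "english_pref_share": config.english_pref_share,
        "age_mean": config.age_mean,
        "age_sd": config.age_sd,
        "english_share_labeled": en / (en + sw),
        "discordance": expected_discordance(config),
        "single_message_sex_ratio": config.single_message_sex_ratio,
        **eng,
    }
    for term in config.planted_terms:
        configured[f"planted_rank:{term}"] = 1.0

    rows = []
    for name, value in recovered.items():
        if name not in configured:
            continue
        target = configured[name]
        n = int(ns.get(name, 0)) or 1
        if name == "age_mean":
            half = z * config.age_sd / np.sqrt(n)
        elif name == "age_sd":
            half = z * config.age_sd / np.sqrt(2 * n)
        elif name == "single_message_sex_ratio":
            half = target * 3 * z / np.sqrt(n)  # coarse delta-method bound
        elif name.startswith("planted_rank:"):
            half = 0.0
        else:
            half = _binomial_ci(target, n, z)
        lo, hi = target - half, target + half
        rows.append((name, target, value, lo, hi, bool(lo <= value <= hi)))
    return pd.DataFrame(
        rows, columns=["quantity", "configured", "recovered", "lo", "hi", "passed"]
    )
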
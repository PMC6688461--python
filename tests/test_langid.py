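"""Language identification, weekly imputation, mix and discordance."""

import math

import pytest

from chatmine import resources
from chatmine.errors import EmptyInputError, TrainingError
from chatmine.langid import (
    DiscordanceReport,
    LanguageModel,
    detect_corpus,
    detect_language,
    discordance,
    impute_weekly_language,
    language_mix,
    train_language_model,
)
from chatmine.synthetic import GeneratorConfig, generate_corpus

from conftest import msg, user

GREEK = [
    ("αλφα βητα γαμμα δελτα εψιλον", "el"),
    ("ζητα ητα θητα ιωτα καππα λαμδα", "el"),
]
LATIN = [
    ("alpha beta gamma delta epsilon", "la"),
    ("zeta eta theta iota kappa lambda", "la"),
]


class TestTrainAndDetect:
    def test_disjoint_alphabets_classify_their_own_sentences(self):
        model = train_language_model(GREEK + LATIN)
        for text, label in GREEK + LATIN:
            got, margin = detect_language(model, text)
            assert got == label
            assert margin > model.reliability_threshold

    def test_identical_corpora_give_zero_margin_und(self):
        pairs = [(t, "a") for t, _ in LATIN] + [(t, "b") for t, _ in LATIN]
        model = train_language_model(pairs)
        for text, _ in LATIN:
            label, margin = detect_language(model, text)
            assert label == "und"
            assert margin == pytest.approx(0.0, abs=1e-12)

    def test_empty_text_is_und(self):
        model = train_language_model(GREEK + LATIN)
        assert detect_language(model, "") == ("und", 0.0)
        assert detect_language(model, None) == ("und", 0.0)

    def test_digits_only_text_is_und(self):
        model = train_language_model(GREEK + LATIN)
        label, _ = detect_language(model, "0712345678")
        assert label == "und"

    def test_empty_language_rejected(self):
        with pytest.raises(TrainingError):
            train_language_model([("abc", "a"), ("", "b")])

    def test_serialization_round_trip_preserves_classifications(self, tmp_path):
        model = resources.default_language_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LanguageModel.from_json(path)
        tests = [
            "what is the best method of family planning",
            "nataka kujua kuhusu uzazi wa mpango",
            "side effects of the injection",
            "siku salama ni zipi kwa mwanamke",
            "0712345678",
        ]
        for text in tests:
            assert detect_language(model, text) == detect_language(back, text)

    def test_default_model_separates_study_languages(self):
        model = resources.default_language_model()
        assert detect_language(model, "how can i prevent pregnancy")[0] == "en"
        assert detect_language(model, "njia bora ya kuzuia mimba ni ipi")[0] == "sw"

    def test_end_to_end_accuracy_on_synthetic_messages(self):
        """>= 99% label accuracy for generated messages of >= 20 characters."""
        corpus, truth = generate_corpus(GeneratorConfig(n_users=800, seed=5))
        model = resources.default_language_model()
        labels = dict(zip(truth.messages.message_id, truth.messages.true_language))
        n = ok = 0
        for m in corpus.inbound():
            true = labels[m.message_id]
            if true == "und" or len(m.body) < 20:
                continue
            n += 1
            ok += detect_language(model, m.body)[0] == true
        assert n > 500
        assert ok / n >= 0.99


class TestWeeklyImputation:
    def test_worked_example_six_en_two_sw_two_und(self, make_corpus):
        """A week with 6 en / 2 sw / 2 und inbound → the 2 und become en."""
        messages = (
            [msg(i, hours=i, language="en") for i in range(6)]
            + [msg(i, hours=i, language="sw") for i in range(6, 8)]
            + [msg(i, hours=i, language="und") for i in range(8, 10)]
        )
        corpus = impute_weekly_language(make_corpus(messages))
        langs = [m.language for m in corpus.messages]
        assert langs.count("en") == 8
        assert langs.count("sw") == 2
        assert "und" not in langs

    def test_all_und_week_stays_und(self, make_corpus):
        corpus = make_corpus([msg(i, hours=i, language="und") for i in range(3)])
        impute_weekly_language(corpus)
        assert all(m.language == "und" for m in corpus.messages)

    def test_weekly_tie_falls_back_to_overall_dominant(self, make_corpus):
        # week 1: 2 en / 2 sw / 1 und; earlier weeks make en dominant overall
        week1 = (
            [msg(1, hours=0, language="en"), msg(2, hours=1, language="en")]
            + [msg(3, hours=2, language="sw"), msg(4, hours=3, language="sw")]
            + [msg(5, hours=4, language="und")]
        )
        earlier = [msg(i, hours=-24 * 14 + i, language="en") for i in (6, 7, 8)]
        corpus = make_corpus(week1 + earlier)
        impute_weekly_language(corpus)
        assert corpus.messages[4].language == "en"

    def test_double_tie_stays_und(self, make_corpus):
        corpus = make_corpus(
            [
                msg(1, hours=0, language="en"),
                msg(2, hours=1, language="sw"),
                msg(3, hours=2, language="und"),
            ]
        )
        impute_weekly_language(corpus)
        assert corpus.messages[2].language == "und"

    def test_outbound_untouched_and_idempotent(self, make_corpus):
        messages = [
            msg(1, hours=0, language="en"),
            msg(2, hours=1, language="und"),
            msg(3, hours=2, direction="outbound", agent="a1"),
        ]
        corpus = make_corpus(messages)
        impute_weekly_language(corpus)
        first = [m.language for m in corpus.messages]
        impute_weekly_language(corpus)
        assert [m.language for m in corpus.messages] == first
        assert corpus.messages[2].language is None


class TestMixAndDiscordance:
    def test_mix_hand_computation(self, make_corpus):
        corpus = make_corpus(
            [
                msg(1, language="en"),
                msg(2, language="en"),
                msg(3, language="sw"),
                msg(4, language="und"),
            ]
        )
        assert language_mix(corpus) == {"en": 50.0, "sw": 25.0, "und": 25.0}

    def test_mix_all_english(self, make_corpus):
        corpus = make_corpus([msg(i, language="en") for i in range(3)])
        mix = language_mix(corpus)
        assert mix["en"] == 100.0 and mix["sw"] == 0.0

    def test_mix_shares_sum_to_100(self, make_corpus):
        corpus, _ = generate_corpus(GeneratorConfig(n_users=100, seed=2))
        detect_corpus(corpus, resources.default_language_model())
        impute_weekly_language(corpus)
        assert sum(language_mix(corpus).values()) == pytest.approx(100.0)

    def test_no_inbound_raises(self, make_corpus):
        corpus = make_corpus([msg(1, direction="outbound", agent="a1")])
        with pytest.raises(EmptyInputError):
            language_mix(corpus)

    def test_discordance_hand_computation(self, make_corpus):
        corpus = make_corpus(
            [msg(1, "a", language="en"), msg(2, "a", language="sw")],
            users=[user("a", pref="en")],
        )
        rep = discordance(corpus)
        assert rep.pct_messages_discordant == 50.0
        assert rep.pct_users_any_discordant == 100.0

    def test_concordant_corpus_reports_zero(self, make_corpus):
        corpus = make_corpus(
            [msg(1, "a", language="en")], users=[user("a", pref="en")]
        )
        rep = discordance(corpus)
        assert rep.pct_messages_discordant == 0.0
        assert rep.pct_users_any_discordant == 0.0

    def test_unknown_preferences_leave_report_undefined(self, make_corpus):
        corpus = make_corpus([msg(1, "a", language="en")], users=[user("a")])
        rep = discordance(corpus)
        assert rep == DiscordanceReport(None, None, 0, 0, defined=False)
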
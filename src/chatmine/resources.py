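"""Access to packaged data files.

The seed corpora are synthetic health-information texts written for this
package (one per study language) used to train the default language model;
they are compositions, not excerpts of any real chat corpus.  Stop lists,
the lemma table, the synonym map and the English wordlist are shipped in the
same CSV dialects the loaders accept for external files, so user-supplied
configuration is a drop-in replacement.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .langid import LanguageModel, train_language_model
from .normalize import (
    EditDistanceSuggester,
    StopList,
    SynonymMap,
    load_lemma_table,
    load_stoplist,
    load_synonym_map,
)

_DATA = resources.files("chatmine") / "data"


def _path(name: str):
    return _DATA / name


def seed_corpus(language: str) -> str:
    """Synthetic seed text for ``en`` or ``sw`` (>= 2000 characters)."""
    return _path(f"seed_{language}_synthetic.txt").read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def default_language_model() -> LanguageModel:
    """Character 2–4-gram model trained on the packaged seed corpora."""
    pairs = []
    for lang in ("en", "sw"):
        for line in seed_corpus(lang).splitlines():
            if line.strip():
                pairs.append((line, lang))
    return train_language_model(pairs)


@lru_cache(maxsize=None)
def english_stoplists() -> tuple[StopList, ...]:
    with resources.as_file(_path("stop_en.csv")) as p:
        return tuple(load_stoplist(p))


@lru_cache(maxsize=None)
def swahili_stoplists() -> tuple[StopList, ...]:
    with resources.as_file(_path("stop_sw.csv")) as p:
        return tuple(load_stoplist(p))


@lru_cache(maxsize=None)
def default_lemma_table() -> dict[str, str]:
    with resources.as_file(_path("lemma_en.csv")) as p:
        return load_lemma_table(p)


@lru_cache(maxsize=None)
def default_synonym_map() -> SynonymMap:
    with resources.as_file(_path("synonyms_en.csv")) as p:
        return load_synonym_map(p)


@lru_cache(maxsize=None)
def english_wordlist() -> frozenset[str]:
    text = _path("wordlist_en.txt").read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def default_suggester() -> EditDistanceSuggester:
    """Offline edit-distance-1 suggester over the packaged wordlist."""
    return EditDistanceSuggester(english_wordlist())
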
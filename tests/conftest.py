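from __future__ import annotations

from datetime import date, datetime, timezone

import pytest

from emomonitor.corpus_io import Corpus, Post
from emomonitor.lexicon import (
    Lexicon,
    LexiconEntry,
    apply_cleaning,
    compile_matcher,
    load_demo_cleaning_rules,
    load_demo_lexicon,
)


@pytest.fixture(scope="session")
def demo_lexicon() -> Lexicon:
    return load_demo_lexicon()


@pytest.fixture(scope="session")
def cleaned_lexicon(demo_lexicon) -> Lexicon:
    return apply_cleaning(demo_lexicon, load_demo_cleaning_rules(), "derstandard")


@pytest.fixture(scope="session")
def cleaned_matcher(cleaned_lexicon):
    return compile_matcher(cleaned_lexicon)


@pytest.fixture()
def tiny_lexicon() -> Lexicon:
    """Two categories, stems, an exact word, a phrase, and one exception."""
    return Lexicon(
        categories=("anxiety", "prosocial"),
        entries=(
            LexiconEntry("angst*", "anxiety"),
            LexiconEntry("panik", "anxiety"),
            LexiconEntry("dienst*", "prosocial"),
            LexiconEntry("teilt mit", "prosocial"),
        ),
        exceptions={"prosocial": frozenset({"dienstag"})},
    )


def make_post(i: int, text: str, day: date = date(2020, 3, 16), platform: str = "test", **kw) -> Post:
    return Post(
        id=f"p{i}",
        platform=platform,
        timestamp=datetime(day.year, day.month, day.day, 12, 0, min(i, 59), tzinfo=timezone.utc),
        text=text,
        **kw,
    )


@pytest.fixture()
def small_corpus() -> Corpus:
    posts = [
        make_post(1, "Ich habe Angst vor der Zukunft", user_id="u1"),
        make_post(2, "Heute ist ein guter Tag", user_id="u2"),
        make_post(3, "Panik! Nur Panik!", day=date(2020, 3, 17), user_id="u1"),
        make_post(4, "", day=date(2020, 3, 17)),
    ]
    return Corpus.from_posts(posts, platform="test")
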
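"""Lexicon parsing, tokenization, cleaning rules, and matcher semantics."""
from __future__ import annotations

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emomonitor.lexicon import (
    CleaningRule,
    DicParseError,
    Lexicon,
    LexiconEntry,
    apply_cleaning,
    compile_matcher,
    load_demo_cleaning_rules,
    load_demo_lexicon,
    match_tokens,
    parse_dic,
    tokenize,
)
from helpers import naive_match, random_lexicon, random_tokens


# --------------------------------------------------------------------------- #
# tokenize


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Ich habe Angst!", ["ich", "habe", "angst"]),
        ("gute Besserung @user https://x.y #hoffnung", ["gute", "besserung", "hoffnung"]),
        ("", []),
        ("   \t\n", []),
        ("Bäume, Größe & Fuß", ["bäume", "größe", "fuß"]),
        ("covid19 2020 abc123def", ["covid", "abc", "def"]),
        ("www.example.org bleibt", ["bleibt"]),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


# --------------------------------------------------------------------------- #
# .dic parsing


def test_parse_minimal_dic():
    lex = parse_dic(io.StringIO("%\n1\tanxiety\n%\nangst*\t1\npanik\t1\n"))
    assert lex.categories == ("anxiety",)
    assert {e.pattern for e in lex.entries} == {"angst*", "panik"}


def test_parse_empty_entry_section():
    lex = parse_dic(io.StringIO("%\n1\tanxiety\n2\tanger\n%\n"))
    assert lex.categories == ("anxiety", "anger")
    assert lex.entries == ()


def test_parse_unknown_category_id_fails():
    with pytest.raises(DicParseError, match="unknown category id"):
        parse_dic(io.StringIO("%\n1\tanxiety\n%\nangst*\t9\n"))


def test_parse_missing_header_delimiters_fails():
    with pytest.raises(DicParseError, match="%"):
        parse_dic(io.StringIO("1\tanxiety\nangst*\t1\n"))


def test_parse_multi_category_entry_and_dedup(caplog):
    text = "%\n1\tanxiety\n2\tanger\n%\nterror*\t1\t2\nterror*\t1\n"
    with caplog.at_level("WARNING"):
        lex = parse_dic(io.StringIO(text))
    cats = {e.category for e in lex.entries if e.pattern == "terror*"}
    assert cats == {"anxiety", "anger"}
    assert len(lex.entries) == 2  # duplicate silently dropped
    assert "duplicate" in caplog.text


def test_demo_lexicon_loads():
    lex = load_demo_lexicon()
    assert set(lex.categories) == {"anxiety", "anger", "sad", "posemo", "social", "prosocial"}
    assert all(len(lex.entries_for(c)) >= 15 for c in lex.categories)


# --------------------------------------------------------------------------- #
# entry / lexicon validation


@pytest.mark.parametrize("bad", ["", "*", "a*b", "a**", "zwei wort*", "a  b", " a"])
def test_invalid_patterns_rejected(bad):
    with pytest.raises(ValueError):
        LexiconEntry(bad, "c")


def test_duplicate_entry_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        Lexicon(("c",), (LexiconEntry("a", "c"), LexiconEntry("a", "c")))


def test_exception_must_be_wildcard_free():
    with pytest.raises(ValueError, match="wildcard-free"):
        Lexicon(("c",), (), {"c": frozenset({"tok*"})})


# --------------------------------------------------------------------------- #
# cleaning


def test_remove_entry_drops_pattern(tiny_lexicon):
    rules = [CleaningRule("remove_entry", "anxiety", "angst*")]
    out = apply_cleaning(tiny_lexicon, rules, "derstandard")
    assert ("angst*", "anxiety") not in {(e.pattern, e.category) for e in out.entries}
    # input lexicon untouched
    assert ("angst*", "anxiety") in {(e.pattern, e.category) for e in tiny_lexicon.entries}


def test_add_exception_blocks_token_but_not_stem(tiny_lexicon):
    rules = [CleaningRule("add_exception", "prosocial", "dienstpflicht")]
    out = apply_cleaning(tiny_lexicon, rules, "derstandard")
    m = compile_matcher(out)
    counts, _ = m.match(["dienstpflicht"])
    assert counts["prosocial"] == 0
    counts, _ = m.match(["dienste"])
    assert counts["prosocial"] == 1


def test_platform_scoped_rule_skipped(tiny_lexicon):
    rules = [CleaningRule("remove_entry", "prosocial", "dienst*", platform_scope="twitter")]
    out = apply_cleaning(tiny_lexicon, rules, "derstandard")
    assert out == tiny_lexicon
    out_tw = apply_cleaning(tiny_lexicon, rules, "twitter")
    assert ("dienst*", "prosocial") not in {(e.pattern, e.category) for e in out_tw.entries}


def test_empty_rule_list_is_identity(tiny_lexicon):
    assert apply_cleaning(tiny_lexicon, [], "x") == tiny_lexicon


def test_removing_absent_entry_warns_not_errors(tiny_lexicon, caplog):
    with caplog.at_level("WARNING"):
        out = apply_cleaning(tiny_lexicon, [CleaningRule("remove_entry", "anxiety", "fehlt*")], "x")
    assert out == tiny_lexicon
    assert "not present" in caplog.text


def test_cleaning_idempotent():
    lex = load_demo_lexicon()
    rules = load_demo_cleaning_rules()
    once = apply_cleaning(lex, rules, "derstandard")
    # absent-removal warnings aside, the result is a fixed point
    assert apply_cleaning(once, rules, "derstandard") == once


# --------------------------------------------------------------------------- #
# matching


def test_match_basic_stem(tiny_lexicon):
    m = compile_matcher(tiny_lexicon)
    ps = match_tokens(m, ["ich", "habe", "angst"])
    assert ps.counts["anxiety"] == 1
    assert ps.token_count == 3
    assert dict(ps.matched_terms["anxiety"]) == {"angst*": 1}


def test_exception_blocks_stem_match(tiny_lexicon):
    m = compile_matcher(tiny_lexicon)
    counts, _ = m.match(["dienstag"])
    assert counts["prosocial"] == 0
    counts, _ = m.match(["dienstags"])  # not in the exception set
    assert counts["prosocial"] == 1


def test_phrase_matches_consecutive_tokens(tiny_lexicon):
    m = compile_matcher(tiny_lexicon)
    counts, matched = m.match(["er", "teilt", "mit", "dass"])
    assert counts["prosocial"] == 1
    assert dict(matched["prosocial"]) == {"teilt mit": 1}
    counts, _ = m.match(["teilt", "und", "mit"])  # non-consecutive
    assert counts["prosocial"] == 0


def test_single_tokens_never_match_phrase_only_lexicon():
    lex = Lexicon(("c",), (LexiconEntry("guten morgen", "c"),))
    m = compile_matcher(lex)
    counts, _ = m.match(["guten"])
    assert counts["c"] == 0


def test_empty_lexicon_matches_nothing():
    m = compile_matcher(Lexicon(("c",), ()))
    counts, _ = m.match(["alles", "mögliche"])
    assert counts == {"c": 0}


def test_longest_pattern_wins_within_category():
    lex = Lexicon(("sad",), (LexiconEntry("miss*", "sad"), LexiconEntry("vermiss*", "sad")))
    m = compile_matcher(lex)
    _, matched = m.match(["vermisse"])
    assert dict(matched["sad"]) == {"vermiss*": 1}


def test_token_counts_once_per_category_but_per_each_category():
    lex = Lexicon(
        ("anxiety", "anger"),
        (LexiconEntry("terror*", "anxiety"), LexiconEntry("terror", "anxiety"), LexiconEntry("terror*", "anger")),
    )
    counts, matched = compile_matcher(lex).match(["terror"])
    assert counts == {"anxiety": 1, "anger": 1}
    assert dict(matched["anxiety"]) == {"terror*": 1}  # longest pattern recorded


# --------------------------------------------------------------------------- #
# properties (seeded randomized oracles)


def test_matcher_equals_naive_oracle_randomized():
    rng = random.Random(20200316)
    for _ in range(300):
        lex = random_lexicon(rng)
        tokens = random_tokens(rng)
        m = compile_matcher(lex)
        assert m.match(tokens) == naive_match(lex, tokens)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_exception_dominance(seed):
    """Adding an exception never raises a count and zeroes that token's share."""
    rng = random.Random(seed)
    lex = random_lexicon(rng)
    tokens = random_tokens(rng, max_len=40)
    if not tokens:
        return
    cat = lex.categories[0]
    tok = rng.choice(tokens)
    before, _ = compile_matcher(lex).match(tokens)
    after, _ = compile_matcher(lex.add_exception(cat, tok)).match(tokens)
    assert after[cat] <= before[cat]
    for c in lex.categories:
        if c != cat:
            assert after[c] == before[c]
    only_tok = [t for t in tokens if t == tok]
    got, _ = compile_matcher(lex.add_exception(cat, tok)).match(only_tok)
    assert got[cat] == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_removing_entry_never_increases_counts(seed):
    rng = random.Random(seed)
    lex = random_lexicon(rng)
    if not lex.entries:
        return
    tokens = random_tokens(rng, max_len=40)
    victim = rng.choice(lex.entries)
    before, _ = compile_matcher(lex).match(tokens)
    after, _ = compile_matcher(lex.remove_entry(victim.category, victim.pattern)).match(tokens)
    assert all(after[c] <= before[c] for c in lex.categories)
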
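"""Emotion lexica: the LIWC ``.dic`` dialect, cleaning rules, and token matching.

A lexicon maps lowercase patterns to named emotion categories (anxiety, anger,
sad, posemo, social, prosocial in the bundled demo). A pattern is either an
exact word, a stem with a single trailing ``*`` (prefix match on the whole
token, the LIWC convention), or a multiword phrase of space-separated exact
words. Each category may additionally carry *exceptions*: exact tokens that
must never count for that category even when a stem would match them (e.g.
"klagenfurt" matching the sadness stem "klagen*").

Matching is case-insensitive; both entries and tokens are lowercased. Within a
category a token occurrence counts at most once, and the longest pattern that
fired is recorded as the canonical match.
"""
from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "CleaningRule",
    "DicParseError",
    "parse_dic",
    "load_dic",
    "load_cleaning_rules",
    "apply_cleaning",
    "tokenize",
    "compile_matcher",
    "match_tokens",
    "Matcher",
    "load_demo_lexicon",
    "load_demo_cleaning_rules",
]

_DATA_DIR = Path(__file__).parent / "data"

# --------------------------------------------------------------------------- #
# tokenization

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# letters only (Unicode): umlauts and ß survive, digits and punctuation split
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens of ``text``.

    URLs and @-mentions are dropped entirely; hashtags keep their word with the
    ``#`` stripped; punctuation and digits act as separators. Returns an empty
    list for empty or non-word input.
    """
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    return _WORD_RE.findall(text.lower())


# --------------------------------------------------------------------------- #
# lexicon types


def _validate_pattern(pattern: str) -> None:
    if not pattern:
        raise ValueError("empty pattern")
    stars = pattern.count("*")
    if stars > 1:
        raise ValueError(f"pattern {pattern!r} contains more than one '*'")
    if stars == 1 and not pattern.endswith("*"):
        raise ValueError(f"'*' only allowed in final position: {pattern!r}")
    if pattern == "*":
        raise ValueError("bare '*' pattern would match everything")
    if " " in pattern:
        if stars:
            raise ValueError(f"multiword pattern must not contain '*': {pattern!r}")
        if "  " in pattern or pattern != pattern.strip():
            raise ValueError(f"multiword pattern has stray spaces: {pattern!r}")


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary pattern assigned to one category."""

    pattern: str
    category: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.lower())
        _validate_pattern(self.pattern)

    @property
    def is_stem(self) -> bool:
        return self.pattern.endswith("*")

    @property
    def is_phrase(self) -> bool:
        return " " in self.pattern


@dataclass(frozen=True)
class Lexicon:
    """An ordered set of categories with their entries and exception tokens."""

    categories: tuple[str, ...]
    entries: tuple[LexiconEntry, ...]
    exceptions: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate category names")
        catset = set(self.categories)
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.category not in catset:
                raise ValueError(f"entry {e.pattern!r} references unknown category {e.category!r}")
            key = (e.pattern, e.category)
            if key in seen:
                raise ValueError(f"duplicate entry {key}")
            seen.add(key)
        exc = {c: frozenset(t.lower() for t in toks) for c, toks in dict(self.exceptions).items()}
        for c, toks in exc.items():
            if c not in catset:
                raise ValueError(f"exceptions reference unknown category {c!r}")
            for t in toks:
                if "*" in t:
                    raise ValueError(f"exception token {t!r} must be wildcard-free")
        object.__setattr__(self, "exceptions", exc)

    # -- functional updates (lexica are immutable) --------------------------

    def remove_entry(self, category: str, pattern: str) -> "Lexicon":
        """Return a copy without the (pattern, category) entry; warn if absent."""
        pattern = pattern.lower()
        kept = tuple(e for e in self.entries if not (e.category == category and e.pattern == pattern))
        if len(kept) == len(self.entries):
            logger.warning("remove_entry: %r not present in category %r", pattern, category)
        return Lexicon(self.categories, kept, self.exceptions)

    def add_exception(self, category: str, token: str) -> "Lexicon":
        """Return a copy with ``token`` added to ``category``'s exception set."""
        if category not in self.categories:
            raise ValueError(f"unknown category {category!r}")
        exc = {c: set(v) for c, v in self.exceptions.items()}
        exc.setdefault(category, set()).add(token.lower())
        return Lexicon(self.categories, self.entries, {c: frozenset(v) for c, v in exc.items()})

    def entries_for(self, category: str) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category == category]


# --------------------------------------------------------------------------- #
# .dic parsing


class DicParseError(ValueError):
    """Raised for a malformed ``.dic`` stream; message names the line."""


def parse_dic(stream: IO[str] | Iterable[str]) -> Lexicon:
    """Parse the LIWC ``.dic`` dialect into a :class:`Lexicon`.

    The format is a header block delimited by lines containing only ``%`` with
    ``<category-id>\\t<category-name>`` lines, followed by entry lines
    ``<word-or-stem>\\t<category-id>[\\t<category-id>...]``. Patterns are
    lowercased; duplicates are dropped with a warning; the parsed lexicon has
    no exceptions.
    """
    lines = list(stream)
    delim = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(delim) < 2:
        raise DicParseError("missing '%' header delimiters (need an opening and closing '%' line)")
    start, end = delim[0], delim[1]

    id_to_name: dict[str, str] = {}
    names: list[str] = []
    for i in range(start + 1, end):
        ln = lines[i].strip()
        if not ln:
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise DicParseError(f"line {i + 1}: malformed header line {ln!r}")
        cid, name = parts[0].strip(), parts[1].strip().lower()
        if cid in id_to_name:
            raise DicParseError(f"line {i + 1}: duplicate category id {cid!r}")
        id_to_name[cid] = name
        names.append(name)

    entries: list[LexiconEntry] = []
    seen: set[tuple[str, str]] = set()
    for i in range(end + 1, len(lines)):
        ln = lines[i].rstrip("\n")
        if not ln.strip():
            continue
        parts = [p for p in ln.split("\t") if p.strip()]
        if len(parts) < 2:
            raise DicParseError(f"line {i + 1}: entry line needs a word and at least one category id")
        word = parts[0].strip().lower()
        for cid in parts[1:]:
            cid = cid.strip()
            if cid not in id_to_name:
                raise DicParseError(f"line {i + 1}: unknown category id {cid!r} for entry {word!r}")
            key = (word, id_to_name[cid])
            if key in seen:
                logger.warning("duplicate entry %r for category %r dropped", word, id_to_name[cid])
                continue
            seen.add(key)
            entries.append(LexiconEntry(word, id_to_name[cid]))
    return Lexicon(tuple(names), tuple(entries))


def load_dic(path: str | Path) -> Lexicon:
    with open(path, encoding="utf-8") as fh:
        return parse_dic(fh)


def load_demo_lexicon() -> Lexicon:
    """The bundled open demo lexicon (synthetic stand-in for a licensed LIWC file)."""
    return load_dic(_DATA_DIR / "demo_lexicon.dic")


# --------------------------------------------------------------------------- #
# cleaning rules

_ACTIONS = ("remove_entry", "add_exception")


@dataclass(frozen=True)
class CleaningRule:
    """One lexicon adaptation: drop an entry or blacklist a token for a category."""

    action: str
    category: str
    target: str
    platform_scope: str = "all"

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(f"action must be one of {_ACTIONS}, got {self.action!r}")
        object.__setattr__(self, "target", self.target.lower())
        if self.action == "remove_entry":
            _validate_pattern(self.target)
        elif "*" in self.target or " " in self.target:
            raise ValueError(f"add_exception target must be a single wildcard-free token: {self.target!r}")


def load_cleaning_rules(path: str | Path) -> list[CleaningRule]:
    """Load a YAML/JSON list of ``{action, category, target, platform_scope}``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return []
    if not isinstance(raw, list):
        raise ValueError("cleaning rules file must contain a list of rule mappings")
    return [CleaningRule(**item) for item in raw]


def load_demo_cleaning_rules() -> list[CleaningRule]:
    return load_cleaning_rules(_DATA_DIR / "cleaning_rules.yaml")


def apply_cleaning(lex: Lexicon, rules: Sequence[CleaningRule], platform: str = "all") -> Lexicon:
    """Apply ``rules`` whose scope covers ``platform``; returns a new lexicon.

    Platform-scoped rules (e.g. Twitter-only removals) are skipped unless the
    scope is ``"all"`` or equals ``platform``. Removing an absent entry logs a
    warning rather than failing, because dictionary editions vary.
    """
    out = lex
    for rule in rules:
        if rule.platform_scope not in ("all", platform):
            continue
        if rule.action == "remove_entry":
            out = out.remove_entry(rule.category, rule.target)
        else:
            out = out.add_exception(rule.category, rule.target)
    return out


# --------------------------------------------------------------------------- #
# matching


class Matcher:
    """Compiled matcher over a lexicon; behaviourally identical to a naive
    per-entry scan, compilation is a pure speed optimization.

    Per token and category: an exact single-word entry or a stem prefix fires
    unless the token is in the category's exception set; among firing patterns
    the longest wins (ties broken lexicographically) and is recorded as the
    canonical match. Each multiword entry additionally counts once per
    occurrence of its exact consecutive token sequence.
    """

    def __init__(self, lexicon: Lexicon):
        self.lexicon = lexicon
        self.categories = lexicon.categories
        self._exact: dict[str, dict[str, str]] = {}  # token -> category -> pattern
        stems: dict[str, list[str]] = {c: [] for c in lexicon.categories}
        self._phrases: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for e in lexicon.entries:
            if e.is_phrase:
                self._phrases.setdefault(e.category, []).append((tuple(e.pattern.split()), e.pattern))
            elif e.is_stem:
                stems[e.category].append(e.pattern[:-1])
            else:
                self._exact.setdefault(e.pattern, {})[e.category] = e.pattern
        # longest-first alternation => .match() yields the longest matching stem
        self._stem_re: dict[str, re.Pattern | None] = {}
        for c, ss in stems.items():
            if ss:
                alt = "|".join(re.escape(s) for s in sorted(ss, key=len, reverse=True))
                self._stem_re[c] = re.compile(f"(?:{alt})")
            else:
                self._stem_re[c] = None
        self._exceptions = {c: lexicon.exceptions.get(c, frozenset()) for c in lexicon.categories}
        self._cache: dict[str, tuple[tuple[str, str], ...]] = {}

    def _match_token(self, token: str) -> tuple[tuple[str, str], ...]:
        hit = self._cache.get(token)
        if hit is not None:
            return hit
        out = []
        exact = self._exact.get(token)
        for cat in self.categories:
            if token in self._exceptions[cat]:
                continue
            best = exact.get(cat) if exact else None
            sre = self._stem_re[cat]
            if sre is not None:
                m = sre.match(token)
                if m:
                    stem_pat = m.group(0) + "*"
                    if best is None or (len(stem_pat), stem_pat) > (len(best), best):
                        best = stem_pat
            if best is not None:
                out.append((cat, best))
        res = tuple(out)
        self._cache[token] = res
        return res

    def match(self, tokens: Sequence[str]) -> tuple[dict[str, int], dict[str, Counter]]:
        """Per-category match counts and canonical matched-term multisets."""
        counts = {c: 0 for c in self.categories}
        matched: dict[str, Counter] = {c: Counter() for c in self.categories}
        for tok in tokens:
            for cat, pat in self._match_token(tok):
                counts[cat] += 1
                matched[cat][pat] += 1
        n = len(tokens)
        for cat, plist in self._phrases.items():
            for ptoks, pstr in plist:
                k = len(ptoks)
                occ = sum(1 for i in range(n - k + 1) if tuple(tokens[i : i + k]) == ptoks)
                if occ:
                    counts[cat] += occ
                    matched[cat][pstr] += occ
        return counts, matched


def compile_matcher(lex: Lexicon) -> Matcher:
    return Matcher(lex)


def match_tokens(m: Matcher, tokens: Sequence[str]):
    """Score one token list; returns a :class:`~emomonitor.scoring.PostScore`
    with no post id or date (filled in by corpus scoring)."""
    from .scoring import PostScore

    counts, matched = m.match(tokens)
    return PostScore(post_id="", date=None, token_count=len(tokens), counts=counts, matched_terms=matched)
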
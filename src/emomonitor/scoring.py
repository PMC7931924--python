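"""Score posts against a compiled lexicon and aggregate to daily indicators.

Two daily metric modes are supported, chosen to suit the platform:

``mean_per_post_frequency``
    Per day, the mean over posts of (category matches / tokens in post).
    Normalising by post length suits forum-style platforms with very variable
    post lengths. Zero-token posts are excluded from the mean (the per-post
    frequency is undefined for them).

``proportion_posts_matching``
    Per day, the share of posts containing at least one category match. Suits
    tweet corpora, where upstream aggregators report "tweets containing at
    least one term". Zero-token posts stay in the denominator: a post of only
    a URL is still a non-matching post.

Days with no eligible post are emitted as missing, never as zero.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus_io import Corpus
from .lexicon import CleaningRule, Lexicon, Matcher, apply_cleaning, compile_matcher, load_demo_lexicon, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "MODE_FREQUENCY",
    "MODE_PROPORTION",
    "MODES",
    "PostScore",
    "DailyIndicator",
    "score_corpus",
    "aggregate_daily",
    "category_term_counts",
    "indicators_to_frame",
    "frame_to_indicators",
    "write_indicators",
    "read_indicators",
    "default_mode_for_platform",
    "LexiconScorer",
]

MODE_FREQUENCY = "mean_per_post_frequency"
MODE_PROPORTION = "proportion_posts_matching"
MODES = (MODE_FREQUENCY, MODE_PROPORTION)

DEFAULT_TIMEZONE = "Europe/Vienna"


def default_mode_for_platform(platform: str) -> str:
    """Frequency averaging for forum-style corpora, post proportion for tweets."""
    return MODE_PROPORTION if platform.lower() == "twitter" else MODE_FREQUENCY


@dataclass
class PostScore:
    """Per-post match counts and the canonical patterns that fired."""

    post_id: str
    date: Date | None
    token_count: int
    counts: dict[str, int]
    matched_terms: dict[str, Counter]

    def __post_init__(self) -> None:
        for c, n in self.counts.items():
            terms = self.matched_terms.get(c, Counter())
            if n != sum(terms.values()):
                raise ValueError(f"category {c!r}: count {n} != matched-term total {sum(terms.values())}")


@dataclass(frozen=True)
class DailyIndicator:
    """One (date, category) indicator value under a declared metric mode."""

    date: Date
    category: str
    mode: str
    value: float
    n_posts: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"indicator value {self.value} outside [0, 1]")
        if self.n_posts < 1:
            raise ValueError("days with zero posts are emitted as missing, not as indicators")


def score_corpus(corpus: Corpus, matcher: Matcher, timezone: str = DEFAULT_TIMEZONE) -> list[PostScore]:
    """One :class:`PostScore` per post, order preserved; dates are local
    calendar days in ``timezone`` (Vienna by default — the monitored platforms
    are Austrian)."""
    tz = ZoneInfo(timezone)
    out: list[PostScore] = []
    for p in corpus.posts:
        tokens = tokenize(p.text)
        counts, matched = matcher.match(tokens)
        out.append(
            PostScore(
                post_id=p.id,
                date=p.timestamp.astimezone(tz).date(),
                token_count=len(tokens),
                counts=counts,
                matched_terms=matched,
            )
        )
    return out


def aggregate_daily(scores: Sequence[PostScore], category: str, mode: str) -> list[DailyIndicator]:
    """Collapse per-post scores into one indicator per calendar day.

    Under ``mean_per_post_frequency`` a day whose posts are all zero-token is
    dropped (logged); under ``proportion_posts_matching`` every post counts in
    the denominator.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    by_day: dict[Date, list[PostScore]] = defaultdict(list)
    for s in scores:
        by_day[s.date].append(s)

    out: list[DailyIndicator] = []
    for day in sorted(by_day):
        day_scores = by_day[day]
        if mode == MODE_FREQUENCY:
            freqs = [s.counts[category] / s.token_count for s in day_scores if s.token_count > 0]
            if not freqs:
                logger.info("day %s has only zero-token posts; emitted as missing", day)
                continue
            value, n = float(np.mean(freqs)), len(freqs)
        else:
            n = len(day_scores)
            value = sum(1 for s in day_scores if s.counts[category] >= 1) / n
        out.append(DailyIndicator(day, category, mode, value, n))
    return out


def category_term_counts(
    scores: Sequence[PostScore], period: tuple[Date, Date] | None = None
) -> dict[str, dict[str, int]]:
    """Total occurrences of each canonical pattern per category over ``period``
    (inclusive date bounds; all days when None). Pattern totals per category
    equal the sum of that category's per-post counts."""
    totals: dict[str, Counter] = defaultdict(Counter)
    for s in scores:
        if period is not None and not (period[0] <= s.date <= period[1]):
            continue
        for cat, terms in s.matched_terms.items():
            totals[cat].update(terms)
    return {cat: dict(cnt) for cat, cnt in totals.items()}


# --------------------------------------------------------------------------- #
# indicator (de)serialisation — CSV: date,category,mode,value,n_posts


def indicators_to_frame(indicators: Iterable[DailyIndicator]) -> pd.DataFrame:
    rows = [(i.date.isoformat(), i.category, i.mode, i.value, i.n_posts) for i in indicators]
    return pd.DataFrame(rows, columns=["date", "category", "mode", "value", "n_posts"])


def frame_to_indicators(df: pd.DataFrame) -> list[DailyIndicator]:
    return [
        DailyIndicator(Date.fromisoformat(str(r.date)), r.category, r.mode, float(r.value), int(r.n_posts))
        for r in df.itertuples()
    ]


def write_indicators(indicators: Iterable[DailyIndicator], path: str | Path) -> None:
    indicators_to_frame(indicators).to_csv(path, index=False)


def read_indicators(path: str | Path) -> list[DailyIndicator]:
    return frame_to_indicators(pd.read_csv(path, dtype={"date": str, "category": str, "mode": str}))


# --------------------------------------------------------------------------- #
# sklearn-style estimator


class LexiconScorer(BaseEstimator, TransformerMixin):
    """Dictionary scorer with a vectorizer-like transform surface.

    ``fit`` compiles the (optionally cleaned) lexicon into a matcher;
    ``transform`` maps an iterable of raw texts to an ``(n_texts,
    n_categories)`` integer count matrix, so the scorer composes with sklearn
    pipelines. :meth:`score_corpus` returns the richer per-post records the
    monitoring pipeline consumes.

    Parameters
    ----------
    lexicon:
        A :class:`~emomonitor.lexicon.Lexicon`; the bundled demo lexicon when
        None.
    rules:
        Cleaning rules applied at fit time, scoped by ``platform``.
    platform:
        Platform name used for rule scoping and the default metric mode.
    timezone:
        IANA zone used to bin posts into calendar days.
    """

    def __init__(
        self,
        lexicon: Lexicon | None = None,
        rules: Sequence[CleaningRule] | None = None,
        platform: str = "all",
        timezone: str = DEFAULT_TIMEZONE,
    ):
        self.lexicon = lexicon
        self.rules = rules
        self.platform = platform
        self.timezone = timezone

    def fit(self, X=None, y=None) -> "LexiconScorer":
        lex = self.lexicon if self.lexicon is not None else load_demo_lexicon()
        if self.rules:
            lex = apply_cleaning(lex, self.rules, self.platform)
        self.lexicon_ = lex
        self.matcher_ = compile_matcher(lex)
        self.categories_ = list(lex.categories)
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        if not hasattr(self, "matcher_"):
            raise AttributeError("LexiconScorer is not fitted; call fit() first")
        rows = []
        for text in X:
            counts, _ = self.matcher_.match(tokenize(text))
            rows.append([counts[c] for c in self.categories_])
        return np.asarray(rows, dtype=np.int64).reshape(-1, len(self.categories_))

    def score_corpus(self, corpus: Corpus) -> list[PostScore]:
        if not hasattr(self, "matcher_"):
            raise AttributeError("LexiconScorer is not fitted; call fit() first")
        return score_corpus(corpus, self.matcher_, timezone=self.timezone)
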
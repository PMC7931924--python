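"""Synthetic post corpora with known ground truth.

The generator emulates the statistical structure a weekday-corrected emotion
monitor has to recover — per-category base emission rates, multiplicative
weekday effects, and dated multiplicative event spikes — without attempting
realistic German grammar. Each post is a bag of i.i.d. tokens: with
probability ``rate_c(day)`` a token is drawn uniformly from category *c*'s
surface forms (inflections of demo-lexicon stems included, so prefix matching
is exercised), otherwise from a background vocabulary that matches nothing.

Because emission is per *token*, both daily metric modes have closed-form
expectations: the mean per-post frequency of category *c* on a day is exactly
``rate_c(day)``, and the probability that a length-``L`` post matches at
least once is ``1 - (1 - rate_c)**L``.

Randomness is derived from a single seed; every day gets its own deterministic
substream keyed by (seed, day ordinal), so editing the period does not
reshuffle earlier days.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np

from .corpus_io import Corpus, Post
from .lexicon import (
    Lexicon,
    Matcher,
    apply_cleaning,
    compile_matcher,
    load_demo_cleaning_rules,
    load_demo_lexicon,
)

logger = logging.getLogger(__name__)

__all__ = ["EventEffect", "SyntheticConfig", "GroundTruth", "generate_corpus", "generate_reference_corpus", "build_surface_forms"]

_WEEKDAY_ALIASES = {n: i for i, n in enumerate(("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"))}

# category base emission probabilities per token; anxiety matches the rate the
# event-recovery simulations are run at, the others follow the relative
# prevalence ordering typical of emotion dictionaries on news-forum text
DEFAULT_BASE_RATE = {
    "anxiety": 0.02,
    "anger": 0.02,
    "sad": 0.02,
    "posemo": 0.04,
    "social": 0.05,
    "prosocial": 0.01,
}

_STEM_SUFFIXES = ("", "e", "en", "er")


@dataclass(frozen=True)
class EventEffect:
    """A dated multiplicative spike on one category's emission rate."""

    start: Date
    end: Date
    category: str
    effect: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end before start")
        if not self.effect > 0:
            raise ValueError("event effect must be > 0")

    def active(self, day: Date) -> bool:
        return self.start <= day <= self.end


@dataclass
class SyntheticConfig:
    seed: int
    period: tuple[Date, Date]
    platform: str = "synthetic"
    posts_per_day: int = 2000
    mean_tokens_per_post: float = 12.0
    background_vocab_size: int = 5000
    base_rate: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATE))
    weekday_multipliers: Mapping[int | str, float] = field(default_factory=dict)
    events: Sequence[EventEffect] = ()
    n_users: int | None = None
    timezone: str = "Europe/Vienna"

    def __post_init__(self) -> None:
        if self.period[1] < self.period[0]:
            raise ValueError("period end before start")
        if self.posts_per_day < 1:
            raise ValueError("posts_per_day must be positive")
        if self.mean_tokens_per_post < 1:
            raise ValueError("mean_tokens_per_post must be >= 1")
        mults = {}
        for k, v in dict(self.weekday_multipliers).items():
            w = _WEEKDAY_ALIASES[k] if isinstance(k, str) else int(k)
            if not 0 <= w <= 6:
                raise ValueError(f"weekday index {w} out of range")
            if not v > 0:
                raise ValueError("weekday multipliers must be > 0")
            mults[w] = float(v)
        self.weekday_multipliers = mults
        for c, r in self.base_rate.items():
            if r < 0:
                raise ValueError(f"base rate for {c!r} is negative")
        # per-token total emission probability must stay below 1 on every day
        day = self.period[0]
        while day <= self.period[1]:
            total = sum(self.rates_for_day(day).values())
            if total >= 1:
                raise ValueError(f"total emission probability {total:.3f} >= 1 on {day}")
            day += timedelta(days=1)

    def rates_for_day(self, day: Date) -> dict[str, float]:
        mult = self.weekday_multipliers.get(day.weekday(), 1.0)
        rates = {}
        for c, r in self.base_rate.items():
            eff = r * mult
            for ev in self.events:
                if ev.category == c and ev.active(day):
                    eff *= ev.effect
            rates[c] = eff
        return rates


@dataclass
class GroundTruth:
    """Realized per-day expected emission rates and the generating config."""

    daily_rates: dict[Date, dict[str, float]]
    base_rate: dict[str, float]
    weekday_multipliers: dict[int, float]
    events: tuple[EventEffect, ...]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "daily_rates": {d.isoformat(): r for d, r in sorted(self.daily_rates.items())},
            "base_rate": self.base_rate,
            "weekday_multipliers": {str(k): v for k, v in sorted(self.weekday_multipliers.items())},
            "events": [
                {"start": e.start.isoformat(), "end": e.end.isoformat(), "category": e.category, "effect": e.effect}
                for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def build_surface_forms(lexicon: Lexicon, matcher: Matcher | None = None) -> dict[str, list[str]]:
    """Unambiguous surface forms per category.

    Exact entries contribute themselves; stems contribute a few inflected
    variants (stem, stem+e, +en, +er). A candidate is kept only if the matcher
    scores it as exactly one match in its own category and none elsewhere, so
    generated tokens have exactly the emission semantics the ground truth
    assumes (exception tokens and cross-category stems are filtered out).
    """
    matcher = matcher or compile_matcher(lexicon)
    surfaces: dict[str, list[str]] = {c: [] for c in lexicon.categories}
    for cat in lexicon.categories:
        seen = set()
        for e in lexicon.entries_for(cat):
            if e.is_phrase:
                continue
            cands = [e.pattern[:-1] + s for s in _STEM_SUFFIXES] if e.is_stem else [e.pattern]
            for cand in cands:
                if not cand or cand in seen:
                    continue
                seen.add(cand)
                counts, _ = matcher.match([cand])
                if counts[cat] == 1 and sum(counts.values()) == 1:
                    surfaces[cat].append(cand)
    return surfaces


def _default_lexicon(platform: str) -> Lexicon:
    return apply_cleaning(load_demo_lexicon(), load_demo_cleaning_rules(), platform)


def generate_corpus(config: SyntheticConfig, lexicon: Lexicon | None = None) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus under ``config``; fully reproducible from its seed.

    Post lengths are geometric with the configured mean (support >= 1);
    category tokens are drawn uniformly from the category's unambiguous
    surface forms; everything else is a background token ``w<k>`` that matches
    no dictionary entry.
    """
    lex = lexicon if lexicon is not None else _default_lexicon(config.platform)
    surfaces = build_surface_forms(lex)
    cats = [c for c in lex.categories if config.base_rate.get(c, 0.0) > 0]
    for c in cats:
        if not surfaces[c]:
            raise ValueError(f"category {c!r} has a positive rate but no unambiguous surface forms")
    surface_arrays = {c: np.array(surfaces[c], dtype=object) for c in cats}

    tz = ZoneInfo(config.timezone)
    posts: list[Post] = []
    daily_rates: dict[Date, dict[str, float]] = {}
    day = config.period[0]
    while day <= config.period[1]:
        rng = np.random.default_rng([config.seed, day.toordinal()])
        rates = config.rates_for_day(day)
        daily_rates[day] = {c: rates[c] for c in cats}
        n = config.posts_per_day
        lengths = rng.geometric(1.0 / config.mean_tokens_per_post, size=n)
        total = int(lengths.sum())
        cum = np.cumsum([rates[c] for c in cats])
        draw = rng.random(total)
        cat_idx = np.searchsorted(cum, draw, side="right")  # == len(cats) -> background
        words = np.empty(total, dtype=object)
        bg = cat_idx == len(cats)
        words[bg] = [f"w{k}" for k in rng.integers(config.background_vocab_size, size=int(bg.sum()))]
        for ci, c in enumerate(cats):
            mask = cat_idx == ci
            m = int(mask.sum())
            if m:
                words[mask] = surface_arrays[c][rng.integers(len(surface_arrays[c]), size=m)]
        user_ids = rng.integers(config.n_users, size=n) if config.n_users else None

        day_start = datetime(day.year, day.month, day.day, tzinfo=tz)
        offset = 0
        step = 86400.0 / n
        for i in range(n):
            L = int(lengths[i])
            text = " ".join(words[offset : offset + L])
            offset += L
            posts.append(
                Post(
                    id=f"{config.platform}-{day.isoformat()}-{i:05d}",
                    platform=config.platform,
                    timestamp=day_start + timedelta(seconds=i * step),
                    text=text,
                    user_id=f"u{user_ids[i]}" if user_ids is not None else None,
                )
            )
        day += timedelta(days=1)

    corpus = Corpus.from_posts(posts, platform=config.platform)
    truth = GroundTruth(
        daily_rates=daily_rates,
        base_rate={c: config.base_rate[c] for c in cats},
        weekday_multipliers=dict(config.weekday_multipliers),
        events=tuple(config.events),
    )
    logger.info("generated %d posts over %d day(s)", len(posts), len(daily_rates))
    return corpus, truth


def generate_reference_corpus(config: SyntheticConfig, lexicon: Lexicon | None = None) -> Corpus:
    """An event-free pre-period corpus for baseline estimation."""
    if config.events:
        raise ValueError("a reference corpus must be event-free")
    corpus, _ = generate_corpus(config, lexicon)
    return corpus
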
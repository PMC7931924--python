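"""Descriptive corpus reports, spike exclusion re-analysis, and static output
bundling for a dashboard front end.

The descriptive report mirrors the usual data-source overview table of a
monitoring study: volumes, per-day activity, unique users (where the platform
has them), per-category match fractions under both metric modes, and post
length / per-item thread statistics for liveticker-style corpora.

The exclusion re-analysis attributes an indicator spike to a topic: it counts
category-matching posts in a date window before and after removing every post
containing one of a given list of words, token-exactly. Exclusion matching is
deliberately not prefix-based — the word lists used for this are written out
as explicit inflected forms.
"""
from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from datetime import date as Date, datetime
from pathlib import Path
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

from .baseline import RelativeSeries
from .corpus_io import Corpus
from .divergence import TermDivergence, divergence_to_frame, wordcloud_export
from .lexicon import Matcher, tokenize
from .scoring import (
    DEFAULT_TIMEZONE,
    MODE_FREQUENCY,
    MODE_PROPORTION,
    PostScore,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusReport",
    "descriptive_report",
    "exclusion_reanalysis",
    "bundle_outputs",
    "GOVERNMENT_SPIKE_EXCLUSION_WORDS",
]

# Word list for re-analysing anxiety spikes driven by reporting on government
# communication strategy (chancellor / fear-mongering / leaked-protocol
# vocabulary) rather than by expressed anxiety itself.
GOVERNMENT_SPIKE_EXCLUSION_WORDS = (
    "kurz",
    "kanzler",
    "schüren",
    "angstmache",
    "angstmacherei",
    "panikmache",
    "protokoll",
    "lügen",
    "bewusst",
    "strategie",
    "regierung",
    "politik",
    "bevölkerung",
    "bürger",
)


@dataclass(frozen=True)
class CorpusReport:
    """Descriptive statistics for one corpus (overview-table shape)."""

    platform: str
    n_posts: int
    n_days: int
    mean_posts_per_day: float
    n_unique_users: int | None
    fractions: Mapping[str, Mapping[str, float]]  # mode -> category -> value
    median_post_length: float
    n_items: int | None = None
    posts_per_item_mean: float | None = None
    posts_per_item_sd: float | None = None
    median_first_post_latency_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "platform": self.platform,
            "n_posts": self.n_posts,
            "n_days": self.n_days,
            "mean_posts_per_day": self.mean_posts_per_day,
            "n_unique_users": self.n_unique_users,
            "fractions": {m: dict(v) for m, v in self.fractions.items()},
            "median_post_length": self.median_post_length,
            "n_items": self.n_items,
            "posts_per_item_mean": self.posts_per_item_mean,
            "posts_per_item_sd": self.posts_per_item_sd,
            "median_first_post_latency_s": self.median_first_post_latency_s,
        }


def descriptive_report(
    corpus: Corpus,
    scores: Sequence[PostScore],
    item_timestamps: Mapping[str, datetime] | None = None,
) -> CorpusReport:
    """Compute every overview statistic from the corpus and its scores.

    ``n_unique_users`` is None (not available) when no post carries a user id.
    Per-item statistics are computed when posts carry ``item_id``; first-post
    latency additionally needs ``item_timestamps`` (item id -> publication
    instant), as recovered from liveticker replay.
    """
    if not corpus.posts:
        raise ValueError("cannot report on an empty corpus")
    if len(scores) != len(corpus.posts):
        raise ValueError("scores must be computed from this corpus (length mismatch)")

    days = {s.date for s in scores}
    users = {p.user_id for p in corpus.posts if p.user_id is not None}
    categories = list(scores[0].counts)

    freq_scores = [s for s in scores if s.token_count > 0]
    fractions = {
        MODE_FREQUENCY: {
            c: (
                sum(s.counts[c] / s.token_count for s in freq_scores) / len(freq_scores)
                if freq_scores
                else 0.0
            )
            for c in categories
        },
        MODE_PROPORTION: {
            c: sum(1 for s in scores if s.counts[c] >= 1) / len(scores) for c in categories
        },
    }

    lengths = [len(p.text) for p in corpus.posts]

    n_items = ppm = pps = latency = None
    with_items = [p for p in corpus.posts if p.item_id is not None]
    if with_items:
        per_item: dict[str, list[datetime]] = {}
        for p in with_items:
            per_item.setdefault(p.item_id, []).append(p.timestamp)
        n_items = len(per_item)
        sizes = [len(v) for v in per_item.values()]
        ppm = float(statistics.mean(sizes))
        pps = float(statistics.stdev(sizes)) if len(sizes) > 1 else 0.0
        if item_timestamps:
            lat = [
                (min(ts) - item_timestamps[iid]).total_seconds()
                for iid, ts in per_item.items()
                if iid in item_timestamps
            ]
            if lat:
                latency = float(statistics.median(lat))

    return CorpusReport(
        platform=corpus.platform,
        n_posts=len(corpus.posts),
        n_days=len(days),
        mean_posts_per_day=len(corpus.posts) / len(days),
        n_unique_users=len(users) if users else None,
        fractions=fractions,
        median_post_length=float(statistics.median(lengths)),
        n_items=n_items,
        posts_per_item_mean=ppm,
        posts_per_item_sd=pps,
        median_first_post_latency_s=latency,
    )


def exclusion_reanalysis(
    corpus: Corpus,
    matcher: Matcher,
    category: str,
    date_window: tuple[Date, Date],
    exclusion_words: Sequence[str],
    timezone: str = DEFAULT_TIMEZONE,
) -> tuple[int, int]:
    """Category-matching post counts in a window, before/after word exclusion.

    ``count_before`` is the number of posts in ``date_window`` (inclusive,
    local calendar dates) with at least one match in ``category``;
    ``count_after`` recounts after dropping every post whose token list
    contains any of ``exclusion_words`` (exact token match, no prefixing).
    """
    excl = {w.lower() for w in exclusion_words}
    for w in excl:
        if "*" in w or " " in w:
            raise ValueError(f"exclusion words must be single exact tokens: {w!r}")
    tz = ZoneInfo(timezone)
    lo, hi = date_window
    before = after = 0
    for p in corpus.posts:
        if not (lo <= p.timestamp.astimezone(tz).date() <= hi):
            continue
        tokens = tokenize(p.text)
        counts, _ = matcher.match(tokens)
        if counts.get(category, 0) >= 1:
            before += 1
            if excl.isdisjoint(tokens):
                after += 1
    return before, after


# --------------------------------------------------------------------------- #
# static bundling

_HTML_HEAD = (
    "<!DOCTYPE html>\n<html lang='en'>\n<head><meta charset='utf-8'>"
    "<title>Emotion monitor</title></head>\n<body>\n"
    "<h1>Emotion monitor — static export</h1>\n"
)


def bundle_outputs(
    series: Mapping[str, RelativeSeries],
    divergence_tables: Mapping[str, Sequence[TermDivergence]],
    reports: Sequence[CorpusReport],
    out_dir: str | Path,
) -> list[Path]:
    """Write a deterministic static bundle: per-category series CSVs,
    divergence CSV/JSON word-cloud data, a JSON report, and a self-contained
    index page. Identical inputs produce byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    html = [_HTML_HEAD]
    for cat in sorted(series):
        s = series[cat]
        path = out / f"series_{cat}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("date,category,pct_change,smoothed\n")
            smoothed = "yes" if s.smoothing_window else "no"
            for d, v in zip(s.dates, s.values):
                sv = "" if v != v else f"{v:.6f}"  # NaN -> empty field
                fh.write(f"{d.isoformat()},{cat},{sv},{smoothed}\n")
        written.append(path)
        html.append(f"<h2>Series: {cat}</h2><p>{len(s.dates)} days; see <code>{path.name}</code></p>\n")

    for cat in sorted(divergence_tables):
        recs = list(divergence_tables[cat])
        csv_path = out / f"divergence_{cat}.csv"
        divergence_to_frame(recs).to_csv(csv_path, index=False, float_format="%.6f")
        written.append(csv_path)
        cloud_path = out / f"wordcloud_{cat}.json"
        cloud_path.write_text(
            json.dumps(wordcloud_export(recs), ensure_ascii=False, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(cloud_path)
        if recs:
            html.append(f"<h2>Word cloud: {cat}</h2><p>{len(recs)} terms passed the filter</p>\n")
        else:
            html.append(f"<h2>Word cloud: {cat}</h2><p>no terms passed the filter</p>\n")

    if reports:
        rep_path = out / "report.json"
        rep_path.write_text(
            json.dumps([r.to_dict() for r in reports], ensure_ascii=False, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written.append(rep_path)
        html.append("<h2>Descriptive report</h2><p>see <code>report.json</code></p>\n")

    html.append("</body>\n</html>\n")
    index = out / "index.html"
    index.write_text("".join(html), encoding="utf-8")
    written.append(index)
    logger.info("bundled %d file(s) into %s", len(written), out)
    return written
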
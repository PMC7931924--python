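"""Weekday baselines and percentage-change series.

Posting behaviour has a strong weekly rhythm (people express more positive
affect on weekends, forums are quieter on Sundays), so comparing a monitored
period against a flat reference level confounds weekday composition with real
change. The correction used here estimates one reference level per weekday
from a pre-period corpus and expresses each monitored day as

    pct_change(d) = 100 * (x_d - b_{w(d)}) / b_{w(d)}

where ``x_d`` is the daily indicator and ``b_w`` the baseline of that day's
weekday. Relative change is computed at the daily-aggregate level (per-post
ratios are ill-posed for short posts, where most per-post frequencies are 0);
the per-weekday aggregator is the mean of daily values by default, with the
median available for heavy-tailed references.

Smoothing is a trailing (causal) moving average: the monitor updates daily and
cannot look into the future.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .scoring import DailyIndicator

logger = logging.getLogger(__name__)

__all__ = [
    "WEEKDAY_NAMES",
    "WeekdayBaseline",
    "RelativeSeries",
    "compute_weekday_baseline",
    "relative_change",
    "smooth",
    "streak_lengths",
    "BaselineCorrector",
]

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass(frozen=True)
class WeekdayBaseline:
    """Per-weekday reference levels for one (platform, category, mode).

    ``values`` maps weekday index (Mon=0 .. Sun=6) to a strictly positive
    level; zero baselines are rejected because relative change against them is
    undefined.
    """

    platform: str
    category: str
    mode: str
    values: Mapping[int, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [WEEKDAY_NAMES[w] for w in range(7) if w not in self.values]
        if missing:
            raise ValueError(f"baseline missing weekday(s): {', '.join(missing)}")
        for w, v in self.values.items():
            if not v > 0:
                raise ValueError(f"baseline for {WEEKDAY_NAMES[w]} is {v}; must be > 0")
        object.__setattr__(self, "values", dict(self.values))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "platform": self.platform,
            "category": self.category,
            "mode": self.mode,
            "values": {WEEKDAY_NAMES[w]: v for w, v in sorted(self.values.items())},
            "provenance": dict(self.provenance),
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "WeekdayBaseline":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        values = {WEEKDAY_NAMES.index(k): float(v) for k, v in doc["values"].items()}
        return cls(doc["platform"], doc["category"], doc["mode"], values, doc.get("provenance", {}))


@dataclass(frozen=True)
class RelativeSeries:
    """Percent change per date; NaN marks missing days."""

    category: str
    dates: tuple[Date, ...]
    values: tuple[float, ...]
    smoothing_window: int | None = None

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must align 1:1")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")


def compute_weekday_baseline(
    indicators: Sequence[DailyIndicator],
    platform: str = "",
    aggregator: str = "mean",
    provenance: Mapping[str, str] | None = None,
) -> WeekdayBaseline:
    """Per-weekday aggregate of a reference indicator series.

    The reference must cover every weekday at least once, belong to a single
    (category, mode), and yield a strictly positive level on each weekday.
    """
    if not indicators:
        raise ValueError("reference indicators must be non-empty")
    cats = {i.category for i in indicators}
    modes = {i.mode for i in indicators}
    if len(cats) != 1 or len(modes) != 1:
        raise ValueError(f"reference mixes categories {cats} / modes {modes}; one of each required")
    agg = {"mean": np.mean, "median": np.median}.get(aggregator)
    if agg is None:
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")

    by_weekday: dict[int, list[float]] = {w: [] for w in range(7)}
    for i in indicators:
        by_weekday[i.date.weekday()].append(i.value)
    values: dict[int, float] = {}
    for w in range(7):
        if not by_weekday[w]:
            raise ValueError(f"reference period contains no {WEEKDAY_NAMES[w]}")
        v = float(agg(by_weekday[w]))
        if v == 0:
            raise ValueError(f"{WEEKDAY_NAMES[w]} baseline is 0; relative change undefined")
        values[w] = v
    prov = dict(provenance or {})
    prov.setdefault("period", f"{min(i.date for i in indicators)}/{max(i.date for i in indicators)}")
    prov.setdefault("aggregator", aggregator)
    return WeekdayBaseline(platform, cats.pop(), modes.pop(), values, prov)


def relative_change(indicators: Sequence[DailyIndicator], baseline: WeekdayBaseline) -> RelativeSeries:
    """Daily percent change of ``indicators`` against their weekday baselines.

    The output covers every calendar day from the first to the last indicator
    date; days without an indicator carry NaN.
    """
    if not indicators:
        raise ValueError("indicators must be non-empty")
    cats = {i.category for i in indicators}
    modes = {i.mode for i in indicators}
    if cats != {baseline.category} or modes != {baseline.mode}:
        raise ValueError(
            f"indicator category/mode {cats}/{modes} do not match baseline "
            f"{baseline.category!r}/{baseline.mode!r}"
        )
    by_date = {i.date: i.value for i in indicators}
    start, end = min(by_date), max(by_date)
    dates = [start + timedelta(days=k) for k in range((end - start).days + 1)]
    values = []
    for d in dates:
        if d in by_date:
            b = baseline.values[d.weekday()]
            values.append(100.0 * (by_date[d] - b) / b)
        else:
            values.append(float("nan"))
    return RelativeSeries(baseline.category, tuple(dates), tuple(values))


def smooth(series: RelativeSeries, window: int = 7) -> RelativeSeries:
    """Trailing moving average over the most recent ``window`` available values.

    At the series start the window shrinks to the data available; missing days
    stay missing. ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = np.asarray(series.values, dtype=float)
    out = np.full_like(vals, np.nan)
    recent: list[float] = []
    for i, v in enumerate(vals):
        if np.isnan(v):
            continue
        recent.append(v)
        out[i] = float(np.mean(recent[-window:]))
    return RelativeSeries(series.category, series.dates, tuple(out.tolist()), smoothing_window=window)


def streak_lengths(series: RelativeSeries, direction: str) -> list[tuple[Date, Date, int]]:
    """Maximal runs of consecutive dates strictly above (or below) baseline.

    A run is broken by a missing value, a value of exactly 0, or a gap in the
    calendar. Returns ``(start, end, length_in_days)`` triples.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    keep = (lambda v: v > 0) if direction == "above" else (lambda v: v < 0)
    runs: list[tuple[Date, Date, int]] = []
    run_start: Date | None = None
    prev: Date | None = None
    for d, v in zip(series.dates, series.values):
        ok = not np.isnan(v) and keep(v)
        contiguous = prev is not None and (d - prev).days == 1
        if ok:
            if run_start is None or not contiguous:
                if run_start is not None:
                    runs.append((run_start, prev, (prev - run_start).days + 1))
                run_start = d
        else:
            if run_start is not None:
                runs.append((run_start, prev, (prev - run_start).days + 1))
                run_start = None
        prev = d if ok else None
    if run_start is not None:
        runs.append((run_start, prev, (prev - run_start).days + 1))
    return runs


# --------------------------------------------------------------------------- #
# sklearn-style estimator


class BaselineCorrector(BaseEstimator, TransformerMixin):
    """Weekday-baseline correction as a fit/transform estimator.

    ``fit`` consumes reference-period indicators (one category, one mode) and
    stores the per-weekday levels in ``baseline_``; ``transform`` maps
    monitored indicators of the same category/mode to a percent-change
    :class:`RelativeSeries`, optionally smoothed.
    """

    def __init__(self, aggregator: str = "mean", platform: str = "", smoothing_window: int | None = None):
        self.aggregator = aggregator
        self.platform = platform
        self.smoothing_window = smoothing_window

    def fit(self, X: Sequence[DailyIndicator], y=None) -> "BaselineCorrector":
        self.baseline_ = compute_weekday_baseline(X, platform=self.platform, aggregator=self.aggregator)
        return self

    def transform(self, X: Sequence[DailyIndicator]) -> RelativeSeries:
        if not hasattr(self, "baseline_"):
            raise AttributeError("BaselineCorrector is not fitted; call fit() first")
        series = relative_change(X, self.baseline_)
        if self.smoothing_window is not None:
            series = smooth(series, self.smoothing_window)
        return series
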
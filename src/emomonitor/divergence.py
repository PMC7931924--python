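"""Corpus-divergence statistics behind the word clouds.

For one emotion category, each dictionary term's prevalence is its share of
all matches in that category: ``prob = count(term) / sum(counts)``. Comparing
a focus corpus (e.g. pandemic-period livetickers) with a reference corpus
(e.g. the previous year's articles), the display statistic for a term is the
signed natural-log ratio

    ln(prob_focus / prob_reference)

whose magnitude drives word-cloud size and whose sign drives colour (red =
more prevalent in the focus corpus, blue = less). Natural log: the base only
rescales all sizes uniformly, so the choice is cosmetic.

Probabilities are computed over the *full* count maps; the minimum-count
inclusion filter (10 in both corpora by default) gates display only, not the
normalisation denominator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "TermDivergence",
    "term_probabilities",
    "divergence_table",
    "wordcloud_export",
    "divergence_to_frame",
]

DEFAULT_MIN_COUNT = 10


@dataclass(frozen=True)
class TermDivergence:
    """Signed log-ratio of one term's within-category prevalence."""

    category: str
    pattern: str
    count_focus: int
    count_reference: int
    prob_focus: float
    prob_reference: float
    magnitude: float
    sign: int

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_focus <= 1.0 and 0.0 < self.prob_reference <= 1.0):
            raise ValueError("term probabilities must lie in (0, 1]")
        if self.magnitude < 0:
            raise ValueError("magnitude is an absolute value")


def term_probabilities(counts: Mapping[str, int]) -> dict[str, float]:
    """Within-category term shares: count / total matches in the category."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero counts: no matches to normalize over")
    return {pat: c / total for pat, c in counts.items()}


def divergence_table(
    counts_focus: Mapping[str, int],
    counts_reference: Mapping[str, int],
    category: str = "",
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[TermDivergence]:
    """Per-term divergence records for one category, sorted by magnitude.

    Probabilities come from the full count maps; a record is emitted only for
    terms counted at least ``min_count`` times in *both* corpora. An empty
    result (nothing passes the filter) is valid.
    """
    probs_f = term_probabilities(counts_focus)
    probs_r = term_probabilities(counts_reference)
    records: list[TermDivergence] = []
    for pat in sorted(set(counts_focus) & set(counts_reference)):
        cf, cr = counts_focus[pat], counts_reference[pat]
        if cf < min_count or cr < min_count:
            continue
        log_ratio = math.log(probs_f[pat] / probs_r[pat])
        records.append(
            TermDivergence(
                category=category,
                pattern=pat,
                count_focus=cf,
                count_reference=cr,
                prob_focus=probs_f[pat],
                prob_reference=probs_r[pat],
                magnitude=abs(log_ratio),
                sign=(log_ratio > 0) - (log_ratio < 0),
            )
        )
    records.sort(key=lambda r: (-r.magnitude, r.pattern))
    return records


def wordcloud_export(
    records: Sequence[TermDivergence], size_range: tuple[float, float] = (12.0, 96.0)
) -> list[dict]:
    """Render-ready word-cloud records: display word, pixel size, colour.

    Size scales linearly with magnitude into ``size_range``; red marks terms
    more prevalent in the focus corpus, blue less, grey unchanged. The
    wildcard ``*`` stays in the display word, matching clouds that show stems.
    """
    lo, hi = size_range
    if hi < lo:
        raise ValueError("size_range must be (min, max) with max >= min")
    max_mag = max((r.magnitude for r in records), default=0.0)
    out = []
    for r in records:
        scale = r.magnitude / max_mag if max_mag > 0 else 0.0
        color = {1: "red", -1: "blue", 0: "grey"}[r.sign]
        out.append({"word": r.pattern, "size": lo + (hi - lo) * scale, "color": color, "category": r.category})
    return out


def divergence_to_frame(records: Sequence[TermDivergence]) -> pd.DataFrame:
    """Tabular export: one row per term with counts, shares, magnitude, sign."""
    cloud = wordcloud_export(records)
    rows = [
        {
            "category": r.category,
            "pattern": r.pattern,
            "count_focus": r.count_focus,
            "count_reference": r.count_reference,
            "prob_focus": r.prob_focus,
            "prob_reference": r.prob_reference,
            "magnitude": r.magnitude,
            "sign": r.sign,
            "color": w["color"],
            "size": w["size"],
        }
        for r, w in zip(records, cloud)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "pattern",
            "count_focus",
            "count_reference",
            "prob_focus",
            "prob_reference",
            "magnitude",
            "sign",
            "color",
            "size",
        ],
    )
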
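# Methods

This note documents the models, conventions, and numerical choices behind
`emomonitor`. It is the package's own account; every number quoted here is
computed by the test suite or by `scripts/acceptance.py`.

## Lexicon matching

The matcher implements the LIWC dictionary convention: a lexicon is a set of
(pattern, category) pairs, where a pattern is an exact word, a stem with one
trailing `*` meaning *prefix match on the whole token*, or a space-separated
multiword phrase of exact words. Matching is case-insensitive (both entries
and tokens are lowercased; German nouns are capitalized, so case-sensitive
matching would systematically miss post text). There are no mid-word
wildcards.

Counting semantics, per category:

- a token occurrence counts **once** even when several single-word entries of
  the category fire on it (stem/word duplicates must not inflate counts);
  the longest firing pattern (ties broken lexicographically) is recorded as
  the canonical matched term, so `vermisse` is attributed to `vermiss*`, not
  `miss*`;
- a token may count toward several categories, once per category — the
  categories are analysed independently;
- each multiword entry counts once per occurrence of its exact consecutive
  token sequence;
- per-category *exception tokens* (exact, wildcard-free) veto all single-word
  matches of that token for that category.

The compiled matcher (hash lookups for exact words, a longest-first regex
alternation per category for stems, and a per-token memo table) is a pure
optimization: a randomized equivalence test checks it against a brute-force
per-entry scan on 1,000 random lexicon/token-list pairs, exactly.

**Tokenization** lowercases, drops URLs and @-mentions entirely, strips `#`
from hashtags (the tag word itself is ordinary text), and treats punctuation
and digits as separators; Unicode letters (umlauts, ß) are preserved. No
lemmatization, compound splitting, or negation handling is attempted — the
method is deliberately a transparent surface-form count.

## Lexicon adaptation (cleaning rules)

The bundled `cleaning_rules.yaml` encodes the adaptation of the emotion
dictionary to pandemic-period news text in four groups: (1) words used far
more often by media during the pandemic without expressing the emotion
(`tot*` from sadness; `toete*`, `töt*`, `töte*` from anger; healing-related
words from positive emotion; treatment/service vocabulary from prosocial),
(2) stem mismatches unrelated to the emotion (*Harmonie*, *harmlos* under
`harm*`; *äußerst*), (3) Austria-specific proper nouns and events
(*Klagenfurt* under `klagen*`, *Misstrauensantrag* under `miss*`), and (4)
platform-mechanic words (*teilen*, *teilt mit*) removed only when scoring
Twitter.

Encoding choice: items that are themselves dictionary patterns become
`remove_entry` rules (the whole entry is biased); single tokens that a
legitimately kept stem would match become `add_exception` rules, because the
stem plausibly stays for its other matches (`dienst*` keeps matching
*Dienste* while *Dienstag* is vetoed). Multiword false positives of a stem
cannot be exceptions (exceptions are single tokens), so they are shipped as
removable multiword entries. The rules file is versioned and editable;
applying a rule whose target is absent logs a warning rather than failing,
since dictionary editions differ.

The German LIWC dictionary itself is proprietary and not shipped. The
bundled `demo_lexicon.dic` is a small synthetic demo lexicon (~20 entries per
category, same `.dic` dialect) whose content covers every term the cleaning
rules reference; users supply their own licensed dictionary file for real
analyses. The prosocial category approximates helping / empathy /
cooperation / sharing / volunteering / donating vocabulary.

## Daily indicators

Two metric modes, chosen per platform:

- `mean_per_post_frequency` (forum-style corpora): per day, the mean over
  posts of `matches / tokens`, which normalises for highly variable post
  lengths. Zero-token posts (e.g. a post that is only a URL) are excluded
  from the mean and the day's `n_posts` — the per-post ratio is undefined.
- `proportion_posts_matching` (tweet corpora, where upstream aggregators
  report "tweets containing at least one term"): per day, the share of posts
  with ≥1 match. Zero-token posts stay in the denominator: a URL-only tweet
  is still a non-matching tweet.

Days with no eligible post are emitted as *missing*, never as zero. Posts are
binned into local calendar days, Europe/Vienna by default (the monitored
platforms are Austrian); the zone is configurable.

## Weekday baselines and percent change

Posting and affect have a strong weekly rhythm, so the monitor corrects for
weekday composition: from an event-free reference period, the baseline for
weekday *w* is the **mean of that weekday's daily indicator values**;
relative change on monitored day *d* is `100·(x_d − b_w(d))/b_w(d)`.

Choices made where the design was genuinely open:

- Relative change is computed at the **daily-aggregate** level, not per post:
  per-post relative differences are ill-posed for short posts, where most
  per-post frequencies are exactly 0. The daily series is also what a
  dashboard plots.
- The per-weekday aggregator is the mean (simplest reading of a "baseline");
  the median is available via an option for heavy-tailed references.
  Averaging daily values (rather than pooling all reference posts per
  weekday) is implemented; the two coincide for balanced reference corpora.
- Smoothing is a **trailing** 7-day moving average over the most recent
  available values — the monitor updates daily and cannot see the future; at
  the series start the window shrinks to the data available. A centered
  window would change alignment only, and the window is a parameter.
- A weekday absent from the reference, or a zero weekday mean, is a hard
  error: relative change against it is undefined.

Streaks are maximal runs of consecutive calendar days strictly above (or
below) 0% change; a missing day, an exact 0, or a calendar gap breaks the
run. Strict inequality means a day exactly on baseline ends both kinds of
streak.

## Divergence statistics

For one category, a term's prevalence is its share of all matches in that
category, `p = count(term)/Σ counts`. The word-cloud statistic between a
focus and a reference corpus is the signed log-ratio `ln(p_focus/p_ref)`;
its magnitude drives display size, its sign the colour (red = up in focus,
blue = down, grey = unchanged). Numerical conventions:

- natural log — the base uniformly rescales all sizes, so the choice is
  cosmetic;
- probabilities are computed over the **full** count maps; the ≥10-count
  inclusion filter (in both corpora) gates display only, not the
  normalisation denominator;
- terms are identified by canonical pattern, so `angst*` aggregates all its
  inflections, matching clouds that display stems;
- exact invariants: antisymmetry under corpus swap, scale invariance under
  uniform count scaling, and filter monotonicity; all are tested exactly.

Statistical significance of term shifts (log-odds with priors, G-tests) is
out of scope; the statistic is descriptive.

## Reports and spike attribution

The descriptive report computes corpus volume, days covered, mean posts/day,
unique users (reported as not-available when the platform is anonymous),
per-category match fractions under *both* modes (explicitly labelled, since
overview tables often leave the metric implicit), the median post length in
Unicode characters of the raw text (pre-tokenization), and per-item thread
statistics (mean ± sd posts per item; median latency from item publication
to first post when item timestamps are available from liveticker replay).

`exclusion_reanalysis` recounts category-matching posts in a date window
after dropping every post containing any of a word list. Matching is
token-exact, not prefix-based: such lists are written as explicit inflected
forms, and prefixing would over-exclude. The shipped
`GOVERNMENT_SPIKE_EXCLUSION_WORDS` list covers chancellor /
fear-mongering / leaked-protocol vocabulary for re-analysing spikes driven by
reporting on government communication strategy.

## Synthetic corpora

The generator produces the statistical structure the pipeline must recover,
not realistic language. Each post is a bag of i.i.d. tokens; with probability
`rate_c(day) = base_rate_c · weekday_multiplier_w(day) · Π active event
effects` a token is drawn uniformly from category *c*'s surface forms, else
from a background vocabulary (`w0`…`w4999`) that matches nothing. Token-level
emission makes both metric modes analytically tractable: the expected mean
per-post frequency equals the rate exactly, and the match probability of a
length-L post is `1−(1−rate)^L`.

Surface forms are built from the cleaned demo lexicon — exact entries
contribute themselves, stems contribute a few suffixed inflections
(exercising prefix matching) — and are filtered to forms the matcher scores
as exactly one match in exactly their own category, so ground-truth rates are
uncontaminated by cross-category stems or exception tokens.

Defaults (the study conditions of the validation suite): 2,000 posts/day;
geometric post lengths with mean 12 tokens (short-post regime, median ~8);
base rates anxiety/anger/sad 0.02, posemo 0.04, social 0.05, prosocial 0.01,
reflecting the usual prevalence ordering of these categories on news-forum
text with anxiety at the rate used throughout the event-recovery
simulations; all weekday multipliers 1 unless configured. Timestamps spread
evenly through each local day. A single seed drives everything; each day
uses a substream keyed by (seed, day ordinal), so extending the period never
reshuffles earlier days.

What the generator does **not** emulate: grammar and word order (only phrase
entries depend on order), topic structure, user-level behaviour, bursty
arrival times, platform markup beyond what tokenization removes. Passing
recovery tests therefore demonstrates the pipeline's statistical
correctness, not the construct validity of dictionary scoring on real text.

## Validation problem sizes

The randomized matcher-equivalence check uses 1,000 (lexicon, token-list)
pairs over a 6-letter alphabet (≤50 entries, ≤100 tokens) so that pattern
collisions, exceptions and phrase overlaps occur frequently. Baseline
self-consistency uses a 13-week reference and a 90-day monitored period at
400 posts/day; event and weekday-multiplier recovery use a 4-week reference
and 14-day monitored window at 2,000 posts/day (the monitored scale the
event-size calculation assumes). Recovery assertions use ±3 standard errors
computed from the realized daily values, combining monitored-mean and
baseline-estimation noise. The CLI end-to-end determinism check runs at 120
posts/day. These sizes are the package's validation choices; all scale
linearly if larger replications are wanted.

## Known limitations

- Dictionary methods count surface forms; negation ("keine Angst") and
  irony invert meaning invisibly. Only aggregate signals are meaningful.
- Exception lists veto single tokens only; a false-positive multiword
  context cannot be vetoed, only removed as an entry.
- The weekday baseline assumes the weekly rhythm is stable between reference
  and monitored periods; holidays and structural platform changes (e.g. a
  platform removing anonymous posting) violate this and appear as level
  shifts.
- `streak_lengths` treats the sampled series as exhaustive; a single missing
  day truncates an otherwise continuous streak.
- Percent change against small baselines is noisy; rare categories should be
  monitored under larger aggregation windows or pooled.
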
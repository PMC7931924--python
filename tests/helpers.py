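"""Independent brute-force oracles and random generators shared by the tests.

The matching oracle deliberately re-derives the contract from scratch (scan
every entry for every token) so it stays independent of the compiled matcher
it checks.
"""
from __future__ import annotations

import random
from collections import Counter

from emomonitor.lexicon import Lexicon, LexiconEntry


def naive_match(lexicon: Lexicon, tokens: list[str]) -> tuple[dict[str, int], dict[str, Counter]]:
    """Per-entry scan: the reference semantics for category match counts."""
    counts = {c: 0 for c in lexicon.categories}
    matched: dict[str, Counter] = {c: Counter() for c in lexicon.categories}
    for tok in tokens:
        for cat in lexicon.categories:
            if tok in lexicon.exceptions.get(cat, frozenset()):
                continue
            firing = []
            for e in lexicon.entries:
                if e.category != cat or e.is_phrase:
                    continue
                if e.is_stem:
                    if tok.startswith(e.pattern[:-1]):
                        firing.append(e.pattern)
                elif e.pattern == tok:
                    firing.append(e.pattern)
            if firing:
                best = max(firing, key=lambda p: (len(p), p))
                counts[cat] += 1
                matched[cat][best] += 1
    for e in lexicon.entries:
        if not e.is_phrase:
            continue
        ptoks = e.pattern.split()
        k = len(ptoks)
        occ = sum(1 for i in range(len(tokens) - k + 1) if tokens[i : i + k] == ptoks)
        if occ:
            counts[e.category] += occ
            matched[e.category][e.pattern] += occ
    return counts, matched


_ALPHABET = "abcdäß"


def random_lexicon(rng: random.Random, max_entries: int = 50) -> Lexicon:
    """A small random lexicon over a tiny alphabet, so collisions are common."""
    n_cats = rng.randint(1, 3)
    cats = tuple(f"cat{i}" for i in range(n_cats))
    entries: set[tuple[str, str]] = set()
    for _ in range(rng.randint(1, max_entries)):
        word = "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(1, 4)))
        kind = rng.random()
        if kind < 0.4:
            pattern = word + "*"
        elif kind < 0.5:
            word2 = "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(1, 3)))
            pattern = f"{word} {word2}"
        else:
            pattern = word
        entries.add((pattern, rng.choice(cats)))
    exceptions: dict[str, set[str]] = {}
    for c in cats:
        if rng.random() < 0.5:
            exceptions[c] = {
                "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(1, 4)))
                for _ in range(rng.randint(1, 3))
            }
    return Lexicon(cats, tuple(LexiconEntry(p, c) for p, c in sorted(entries)), exceptions)


def random_tokens(rng: random.Random, max_len: int = 100) -> list[str]:
    return [
        "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(1, 5)))
        for _ in range(rng.randint(0, max_len))
    ]
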
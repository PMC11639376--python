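"""Category lexicon I/O, category-proportion profiles, and dominance scores.

A category lexicon is a LIWC-style dictionary mapping words to psychological
and linguistic categories.  Eight closed-class *function-word* categories
(auxiliary verbs, common adverbs, personal pronouns, impersonal pronouns,
prepositions, negations, conjunctions, quantifiers — articles are dropped
because Chinese has none) carry conversational style; the remaining *content*
categories (emotion, family, health, ...) carry topic/affect signal.

The dominance score of a category t between a high- and a low-engagement
class is the ratio of t's token proportion in the high class to that in the
low class: S_t = type%_high / type%_low.  S_t = 1 means identical usage;
S_t > 1 means the high-engagement class over-uses t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_FUNCTION_CATEGORIES",
    "CategoryLexicon",
    "CategoryProfile",
    "DominanceTable",
    "read_lexicon",
    "write_lexicon",
    "category_profile",
    "dominance_scores",
    "LexiconError",
]

DEFAULT_FUNCTION_CATEGORIES: tuple[str, ...] = (
    "auxverb",
    "adverb",
    "ppron",
    "ipron",
    "prep",
    "negate",
    "conj",
    "quant",
)


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon files."""


@dataclass
class CategoryLexicon:
    """category -> word set map with a designated function-word subset.

    Every function word belongs to exactly one function category; content
    categories may overlap (a word can be both "negemo" and "anx").
    """

    categories: dict[str, frozenset[str]]
    function_categories: tuple[str, ...] = DEFAULT_FUNCTION_CATEGORIES
    _word_cats: dict[str, tuple[str, ...]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        self.function_categories = tuple(self.function_categories)
        missing = [c for c in self.function_categories if c not in self.categories]
        if missing:
            raise LexiconError(f"function categories missing from lexicon: {missing}")
        seen: dict[str, str] = {}
        for cat in self.function_categories:
            for word in self.categories[cat]:
                if word in seen:
                    raise LexiconError(
                        f"function word {word!r} in two function categories: "
                        f"{seen[word]!r} and {cat!r}"
                    )
                seen[word] = cat
        self._word_cats = {}
        for cat in sorted(self.categories):
            for word in self.categories[cat]:
                self._word_cats[word] = self._word_cats.get(word, ()) + (cat,)

    def categories_of(self, word: str) -> tuple[str, ...]:
        return self._word_cats.get(word, ())

    @property
    def words(self) -> frozenset[str]:
        return frozenset(self._word_cats)

    def __len__(self) -> int:
        return len(self.categories)


@dataclass
class CategoryProfile:
    """Per-category token proportions, in percent of ALL tokens pooled.

    ``proportions[c] = 100 * (hits of category c) / token_total``; the
    denominator counts every token, including words outside the lexicon.
    """

    proportions: dict[str, float]
    token_total: int

    def __getitem__(self, category: str) -> float:
        return self.proportions[category]

    def restrict(self, categories: Sequence[str]) -> "CategoryProfile":
        return CategoryProfile(
            {c: self.proportions[c] for c in categories}, self.token_total
        )


@dataclass
class DominanceTable:
    """Category dominance ratios between a high and a low engagement class.

    ``flags[c]`` is "" where defined, "undefined" where the low-class
    proportion is zero with a positive high-class proportion, and
    "degenerate" where both proportions are zero (score 1 by convention).
    """

    scores: dict[str, float]
    flags: dict[str, str]
    numerator_class: str
    denominator_class: str
    high: CategoryProfile | None = None
    low: CategoryProfile | None = None

    def __getitem__(self, category: str) -> float:
        return self.scores[category]

    def to_frame(self) -> pd.DataFrame:
        cats = sorted(self.scores)
        data = {
            "category": cats,
            f"{self.numerator_class}_pct": [
                self.high.proportions[c] if self.high else float("nan") for c in cats
            ],
            f"{self.denominator_class}_pct": [
                self.low.proportions[c] if self.low else float("nan") for c in cats
            ],
            "score": [self.scores[c] for c in cats],
            "flag": [self.flags[c] for c in cats],
        }
        return pd.DataFrame(data)


def read_lexicon(path: str | Path) -> CategoryLexicon:
    """Parse a delimited lexicon file.

    Format: an initial directive line ``#function: cat1,...,cat8`` naming the
    function-word categories, then one line per word: ``word<TAB>cat1,cat2``.
    """
    path = Path(path)
    function_cats: tuple[str, ...] | None = None
    cat_words: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#function:"):
                function_cats = tuple(
                    c.strip() for c in line[len("#function:"):].split(",") if c.strip()
                )
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(f"{path}:{lineno}: expected 'word<TAB>categories'")
            word, cats = parts[0].strip(), [c.strip() for c in parts[1].split(",") if c.strip()]
            if not word or not cats:
                raise LexiconError(f"{path}:{lineno}: empty word or category list")
            for cat in cats:
                cat_words.setdefault(cat, set()).add(word)
    if not cat_words:
        raise LexiconError(f"{path}: no categories found")
    if function_cats is None:
        function_cats = tuple(c for c in DEFAULT_FUNCTION_CATEGORIES if c in cat_words)
    return CategoryLexicon({k: frozenset(v) for k, v in cat_words.items()}, function_cats)


def write_lexicon(lexicon: CategoryLexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#function: " + ",".join(lexicon.function_categories) + "\n")
        for word in sorted(lexicon.words):
            fh.write(word + "\t" + ",".join(lexicon.categories_of(word)) + "\n")


def category_profile(
    docs: Iterable[Sequence[str]], lexicon: CategoryLexicon
) -> CategoryProfile:
    """Pooled category proportions over all tokens of all documents.

    All documents are pooled into one bag; the proportion of category c is
    100 * hits(c) / total tokens.  Proportions are computed over every token
    (lexicon misses count in the denominator), the LIWC convention.
    """
    hits = {cat: 0 for cat in lexicon.categories}
    total = 0
    for doc in docs:
        for token in doc:
            total += 1
            for cat in lexicon.categories_of(token):
                hits[cat] += 1
    if total == 0:
        raise ValueError("cannot profile zero tokens")
    return CategoryProfile({c: 100.0 * n / total for c, n in hits.items()}, total)


def dominance_scores(
    high: CategoryProfile,
    low: CategoryProfile,
    numerator_class: str = "high",
    denominator_class: str = "low",
) -> DominanceTable:
    """Per-category dominance ratios high/low (S_t = type%_high / type%_low).

    A zero low-class proportion with a positive high-class proportion is
    reported as undefined (NaN score, flagged), never imputed; both zero
    yields score 1 by convention, flagged degenerate.
    """
    if set(high.proportions) != set(low.proportions):
        raise ValueError("profiles cover different category sets")
    scores: dict[str, float] = {}
    flags: dict[str, str] = {}
    for cat in high.proportions:
        ph, pl = high.proportions[cat], low.proportions[cat]
        if pl == 0.0 and ph == 0.0:
            scores[cat], flags[cat] = 1.0, "degenerate"
        elif pl == 0.0:
            scores[cat], flags[cat] = float("nan"), "undefined"
        else:
            scores[cat], flags[cat] = ph / pl, ""
    table = DominanceTable(scores, flags, numerator_class, denominator_class, high, low)
    return table
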
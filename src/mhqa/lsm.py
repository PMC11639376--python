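"""Linguistic Style Matching between questions and their answers.

LSM measures how closely two conversation partners align their *style*,
operationalized as the proportions of eight function-word categories.  For a
question q and answer a, the per-category score is

    LSM_t = 1 - |type%_q(t) - type%_a(t)| / (type%_q(t) + type%_a(t) + .0001)

(the .0001 guards the empty-empty case and is part of the published formula);
the pair's LSM is the arithmetic mean over the 8 categories.  Scores lie in
(0, 1], equal to 1 exactly when both proportions coincide.

Pairs are aggregated per (topic, engagement class) and summarized by the mean
with a non-parametric bootstrap percentile confidence interval over pair-level
scores.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import CategoryLexicon, category_profile

__all__ = [
    "LsmScore",
    "LsmSummary",
    "lsm_category",
    "lsm_pair",
    "lsm_by_topic",
    "bootstrap_ci",
]

_EPS = 0.0001  # additive constant in the published LSM denominator


@dataclass
class LsmScore:
    """LSM between one question and one of its answers."""

    question_id: str
    answer_id: str
    per_category: dict[str, float]
    mean: float


@dataclass
class LsmSummary:
    """Mean LSM with bootstrap CI for one (topic, engagement class) cell."""

    topic: object
    engagement_class: str
    n_pairs: int
    mean: float
    ci_low: float
    ci_high: float
    level: float
    replicates: int
    seed: int


def lsm_category(pq: float, pa: float) -> float:
    """Style-matching score for one category from two percentages."""
    return 1.0 - abs(pq - pa) / (pq + pa + _EPS)


def lsm_pair(
    q_tokens: Sequence[str],
    a_tokens: Sequence[str],
    lexicon: CategoryLexicon,
    question_id: str = "q",
    answer_id: str = "a",
) -> LsmScore:
    """LSM between a question and an answer token sequence.

    Function-category proportions are computed per post over ALL tokens of
    that post (content words count in the denominator), then compared
    category by category; the mean over exactly the 8 function categories is
    the pair's LSM.
    """
    if not q_tokens or not a_tokens:
        raise ValueError("cannot compute LSM for an empty token sequence")
    cats = lexicon.function_categories
    pq = category_profile([q_tokens], lexicon).restrict(cats)
    pa = category_profile([a_tokens], lexicon).restrict(cats)
    per_cat = {t: lsm_category(pq[t], pa[t]) for t in cats}
    return LsmScore(
        question_id, answer_id, per_cat, float(np.mean(list(per_cat.values())))
    )


def bootstrap_ci(
    values: Sequence[float], B: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean: (mean, low, high).

    Draws B resamples of size n with replacement and takes the
    (1-level)/2 and 1-(1-level)/2 quantiles of the resample means.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(B, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(low), float(high)


def lsm_by_topic(
    pairs: Iterable[tuple[Sequence[str], Sequence[str], object, str]],
    lexicon: CategoryLexicon,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> list[LsmSummary]:
    """Aggregate pair-level LSM per (topic, engagement class).

    ``pairs`` yields (question_tokens, answer_tokens, topic_label, class);
    each answer is scored against its own question.  Cells are summarized by
    the mean and a pair-level bootstrap CI.  The bootstrap seed of each cell
    is derived from ``seed`` and the cell's (topic, class) key, so summaries
    are invariant to the order in which pairs arrive.
    """
    cells: dict[tuple[object, str], list[float]] = {}
    for q_tokens, a_tokens, topic, cls in pairs:
        score = lsm_pair(q_tokens, a_tokens, lexicon)
        cells.setdefault((topic, cls), []).append(score.mean)
    topics = {t for t, _ in cells}
    classes = {c for _, c in cells}
    for topic in sorted(topics, key=str):
        for cls in sorted(classes):
            if (topic, cls) not in cells:
                warnings.warn(
                    f"no {cls} pairs under topic {topic!r}; summary omitted",
                    stacklevel=2,
                )
    summaries = []
    for (topic, cls) in sorted(cells, key=lambda k: (str(k[0]), k[1])):
        # sort within the cell so summaries are invariant to arrival order
        vals = sorted(cells[(topic, cls)])
        cell_seed = (seed * 1_000_003 + zlib.crc32(f"{topic}|{cls}".encode())) % (2**31)
        mean, low, high = bootstrap_ci(vals, B=B, level=level, seed=cell_seed)
        summaries.append(
            LsmSummary(topic, cls, len(vals), mean, low, high, level, B, cell_seed)
        )
    return summaries


def summaries_to_frame(summaries: Sequence[LsmSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "topic": [s.topic for s in summaries],
            "class": [s.engagement_class for s in summaries],
            "n": [s.n_pairs for s in summaries],
            "mean_lsm": [s.mean for s in summaries],
            "ci_low": [s.ci_low for s in summaries],
            "ci_high": [s.ci_high for s in summaries],
            "level": [s.level for s in summaries],
            "B": [s.replicates for s in summaries],
        }
    )
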
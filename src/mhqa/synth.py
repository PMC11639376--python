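"""Synthetic Q&A corpus generator with planted ground truth.

The generator emulates the statistical structure of a counseling Q&A
platform without attempting fluent language: tokens are symbolic words
carrying lexicon category tags, because every downstream statistic
(category proportions, LSM, LDA, n-gram entropies) is token-based.

Planted structure, each dimension independently controllable:

* **Topics** — each question draws a Dirichlet doc-topic mixture; content
  tokens come from planted topic-word distributions (the LDA generative
  model).  Answers draw content from their question's dominant topic.
* **Engagement** — each post gets a latent class (high / low / mid); reply
  and like counts are drawn from over-dispersed per-class count
  distributions, so the platform's long-tailed counts and the threshold
  rules (replies >= 6 vs == 1; likes >= 10 vs == 0) are both exercised.
* **Category usage** — per-class rate multipliers reweight content words
  tagged with designated categories (e.g. a 1.5x "negemo" boost for
  high-engagement answers), planting known dominance-score effects.
* **Style matching** — each question owns a style vector over the 8
  function-word categories; an answer's style vector is the convex
  combination (1 - m)*base + m*question_style with a per-class matching
  parameter m, making the planted LSM effect analytically predictable.

Bit-reproducible for a (config, seed) pair: one master seed; per-post RNG
streams derived deterministically from (seed, post counter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, Post
from .lexicon import CategoryLexicon, DEFAULT_FUNCTION_CATEGORIES

__all__ = ["LengthSpec", "SynthConfig", "GroundTruth", "generate_lexicon", "generate_corpus"]


@dataclass
class LengthSpec:
    """Token-count distribution: shifted negative binomial, minimum 1.

    ``dispersion`` is the NB shape parameter (smaller = heavier tail).
    """

    mean: float
    dispersion: float = 2.0

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        if self.mean <= 0:  # degenerate spec: always zero (e.g. "no answers")
            return np.zeros(size, dtype=int)
        if not np.isfinite(self.dispersion):  # deterministic length
            return np.full(size, max(1, round(self.mean)), dtype=int)
        mu = max(self.mean - 1.0, 0.01)
        r = self.dispersion
        p = r / (r + mu)
        return 1 + rng.negative_binomial(r, p, size=size)


def _default_engagement_model() -> dict:
    # Count distributions per planted class; over-dispersed (NB) upper tails
    # mirror the platform's long-tailed reply/like histograms.
    return {
        "QHE": {"base": 6, "extra_mean": 4.0, "dispersion": 1.0},
        "QLE": {"base": 1, "extra_mean": 0.0, "dispersion": 1.0},
        "midQ": {"low": 2, "high": 5},  # uniform between thresholds
        "AHE": {"base": 10, "extra_mean": 6.0, "dispersion": 1.0},
        "ALE": {"base": 0, "extra_mean": 0.0, "dispersion": 1.0},
        "midA": {"low": 1, "high": 9},
    }


@dataclass
class SynthConfig:
    """Study conditions for the generated platform corpus.

    Defaults are chosen to mirror the scale relations of a real counseling
    Q&A board at desk scale: ~3.5 answers per question, answer bodies about
    2.4x the length of question bodies, roughly balanced high/low engagement
    extremes with a mid bucket between the thresholds, m_AHE = 0.8 vs
    m_ALE = 0.2 style matching, and content-category boosts for the
    high-engagement classes.
    """

    n_questions: int = 500
    answers_per_question: LengthSpec = field(
        default_factory=lambda: LengthSpec(mean=3.5, dispersion=2.0)
    )
    n_topics: int = 8
    vocab_size: int = 2000
    n_function_words: int = 160
    content_categories: tuple[str, ...] = (
        "negemo", "anx", "family", "motion", "space",
        "achieve", "health", "time", "humans", "biology",
    )
    content_tag_prob: float = 0.6
    two_tag_prob: float = 0.2
    topic_word_conc: float = 0.05
    doc_topic_conc: float = 0.1
    title_len: LengthSpec = field(default_factory=lambda: LengthSpec(mean=12, dispersion=4.0))
    question_len: LengthSpec = field(default_factory=lambda: LengthSpec(mean=140, dispersion=4.0))
    answer_len: LengthSpec = field(default_factory=lambda: LengthSpec(mean=335, dispersion=4.0))
    function_word_rate: float = 0.35
    style_conc: float = 5.0
    style_match: Mapping[str, float] = field(
        default_factory=lambda: {"AHE": 0.8, "ALE": 0.2, "midA": 0.5}
    )
    category_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "AHE": {"negemo": 1.5, "motion": 1.3, "family": 1.3, "space": 1.2},
            "QHE": {"achieve": 1.3, "family": 1.2, "humans": 1.2, "time": 1.2},
            "QLE": {"health": 1.3, "biology": 1.2, "anx": 1.2},
        }
    )
    # The engagement extremes are minorities of the platform traffic: the two
    # classes are roughly balanced against each other but most posts sit
    # between the thresholds, which also keeps the mean like/reply counts
    # near the observed platform marginals (~4 likes, ~3.6 replies).
    class_probs_q: Mapping[str, float] = field(
        default_factory=lambda: {"QHE": 0.25, "QLE": 0.30, "midQ": 0.45}
    )
    class_probs_a: Mapping[str, float] = field(
        default_factory=lambda: {"AHE": 0.06, "ALE": 0.08, "midA": 0.86}
    )
    engagement_model: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_engagement_model
    )
    ahe_min_likes: int = 10  # threshold the planted high class must support

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        for cls, m in self.style_match.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"style_match[{cls!r}] must be in [0, 1]")
        for cls, rates in self.category_rates.items():
            for cat, r in rates.items():
                if r < 0:
                    raise ValueError(f"category rate {cls}/{cat} must be >= 0")
        if self.vocab_size < self.n_function_words + len(self.content_categories):
            raise ValueError(
                "vocab_size too small to populate every function and content category"
            )
        if self.n_function_words < len(DEFAULT_FUNCTION_CATEGORIES):
            raise ValueError("need at least one function word per function category")


@dataclass
class GroundTruth:
    """Planted parameters behind a generated corpus."""

    questions: pd.DataFrame  # id, topic, cls, style_<cat>...
    answers: pd.DataFrame  # id, parent_id, cls, m, style_<cat>...
    topic_word: np.ndarray  # (K, V) planted topic-word distributions
    word_ids: dict[str, int]  # word -> column of topic_word
    config: SynthConfig

    def topic_of(self) -> dict[str, int]:
        return dict(zip(self.questions["id"], self.questions["topic"]))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.questions.to_csv(outdir / "questions_truth.tsv", sep="\t", index=False)
        self.answers.to_csv(outdir / "answers_truth.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        with (outdir / "config.yaml").open("w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def _word(i: int) -> str:
    return f"w{i:05d}"


def generate_lexicon(cfg: SynthConfig, seed: int) -> CategoryLexicon:
    """Deterministic synthetic category lexicon.

    The vocabulary is partitioned into function words (split evenly over the
    8 function categories, one category each) and content words; a content
    word is tagged with one or two content categories with probability
    ``content_tag_prob`` (each category is guaranteed at least one word).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF]))
    fcats = DEFAULT_FUNCTION_CATEGORIES
    n_f = cfg.n_function_words
    cats: dict[str, set[str]] = {c: set() for c in fcats}
    for i in range(n_f):
        cats[fcats[i % len(fcats)]].add(_word(i))
    content_ids = list(range(n_f, cfg.vocab_size))
    ccats = cfg.content_categories
    for c in ccats:
        cats[c] = set()
    # guarantee non-empty content categories
    for j, c in enumerate(ccats):
        cats[c].add(_word(content_ids[j]))
    for i in content_ids[len(ccats):]:
        if rng.random() < cfg.content_tag_prob:
            n_tags = 2 if rng.random() < cfg.two_tag_prob else 1
            for c in rng.choice(len(ccats), size=n_tags, replace=False):
                cats[ccats[c]].add(_word(i))
    return CategoryLexicon({k: frozenset(v) for k, v in cats.items()}, fcats)


def _class_count(rng: np.random.Generator, model: Mapping[str, float]) -> int:
    if "low" in model:  # mid bucket: uniform between thresholds
        return int(rng.integers(int(model["low"]), int(model["high"]) + 1))
    extra = 0
    if model.get("extra_mean", 0.0) > 0:
        r = float(model.get("dispersion", 1.0))
        mu = float(model["extra_mean"])
        extra = int(rng.negative_binomial(r, r / (r + mu)))
    return int(model["base"]) + extra


def _boosted(phi_k: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Reweight a word distribution so each boosted word's probability is
    exactly ``weights * phi`` and only unboosted words absorb the
    renormalization.  This keeps the planted category-proportion ratio equal
    to the configured rate multiplier (up to rare overlapping-tag words),
    so dominance-score recovery has no renormalization bias.  Falls back to
    global renormalization if the boosted mass would reach 1."""
    if np.all(weights == 1.0):
        return phi_k
    boosted = weights != 1.0
    mass = float((phi_k * weights)[boosted].sum())
    rest = float(phi_k[~boosted].sum())
    if mass >= 1.0 or rest <= 0.0:
        w = phi_k * weights
        return w / w.sum()
    out = phi_k * weights
    out[~boosted] = phi_k[~boosted] * (1.0 - mass) / rest
    return out


def generate_corpus(
    cfg: SynthConfig, seed: int, lexicon: CategoryLexicon | None = None
) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its planted ground truth.

    Question bodies mix content tokens (planted topic-word distributions,
    class-boosted) with function tokens drawn from the question's style
    vector at rate ``function_word_rate``; answers reuse the question's
    dominant topic and mix their style vector toward the question's by the
    class matching parameter m.  Post bodies are the tokens joined by single
    spaces, so the whitespace tokenizer recovers them exactly.
    """
    if lexicon is None:
        lexicon = generate_lexicon(cfg, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    fcats = lexicon.function_categories
    n_fc = len(fcats)
    func_words = [sorted(lexicon.categories[c]) for c in fcats]
    content_words = sorted(
        set(_word(i) for i in range(cfg.vocab_size)) - lexicon.words
        | {w for c in cfg.content_categories for w in lexicon.categories[c]}
    )
    word_ids = {w: i for i, w in enumerate(content_words)}
    V_c = len(content_words)
    K = cfg.n_topics
    # planted topic-word distributions over content words
    phi = rng.dirichlet(np.full(V_c, cfg.topic_word_conc), size=K)
    # per-class word weights from category rate multipliers
    class_weights: dict[str, np.ndarray] = {}
    for cls, rates in cfg.category_rates.items():
        w = np.ones(V_c)
        for cat, rate in rates.items():
            for word in lexicon.categories.get(cat, ()):
                if word in word_ids:
                    w[word_ids[word]] *= rate
        class_weights[cls] = w
    ones = np.ones(V_c)

    q_classes = sorted(cfg.class_probs_q)
    q_probs = np.array([cfg.class_probs_q[c] for c in q_classes])
    q_probs = q_probs / q_probs.sum()
    a_classes = sorted(cfg.class_probs_a)
    a_probs = np.array([cfg.class_probs_a[c] for c in a_classes])
    a_probs = a_probs / a_probs.sum()

    def draw_tokens(
        sub: np.random.Generator, length: int, theta: np.ndarray | None,
        topic: int | None, weights: np.ndarray, style: np.ndarray,
    ) -> list[str]:
        n_func = int(sub.binomial(length, cfg.function_word_rate))
        n_content = length - n_func
        toks: list[str] = []
        if n_content > 0:
            if theta is not None:
                topics = sub.choice(K, size=n_content, p=theta)
            else:
                topics = np.full(n_content, topic)
            for k in np.unique(topics):
                n_k = int((topics == k).sum())
                dist = _boosted(phi[k], weights)
                ids = sub.choice(V_c, size=n_k, p=dist)
                toks.extend(content_words[i] for i in ids)
        if n_func > 0:
            cat_ids = sub.choice(n_fc, size=n_func, p=style)
            for c in cat_ids:
                pool = func_words[c]
                toks.append(pool[int(sub.integers(len(pool)))])
        perm = sub.permutation(len(toks))
        return [toks[i] for i in perm]

    posts: list[Post] = []
    q_rows, a_rows = [], []
    counter = 0
    n_high_a = n_high_ok = 0
    for qi in range(cfg.n_questions):
        sub = np.random.default_rng(np.random.SeedSequence([seed, 1, counter]))
        counter += 1
        qid = f"q{qi:05d}"
        theta = sub.dirichlet(np.full(K, cfg.doc_topic_conc))
        topic = int(np.argmax(theta))
        style_q = sub.dirichlet(np.full(n_fc, cfg.style_conc))
        cls = q_classes[int(sub.choice(len(q_classes), p=q_probs))]
        replies = _class_count(sub, cfg.engagement_model[cls])
        weights = class_weights.get(cls, ones)
        L_title = int(cfg.title_len.sample(sub)[0])
        L_body = int(cfg.question_len.sample(sub)[0])
        title = " ".join(draw_tokens(sub, L_title, theta, None, weights, style_q))
        body = " ".join(draw_tokens(sub, L_body, theta, None, weights, style_q))
        posts.append(
            Post(qid, "question", "", title, body, reply_count=replies)
        )
        q_rows.append(
            {"id": qid, "topic": topic, "cls": cls,
             **{f"style_{c}": style_q[j] for j, c in enumerate(fcats)}}
        )
        n_answers = int(cfg.answers_per_question.sample(sub)[0])
        for ai in range(n_answers):
            sub_a = np.random.default_rng(np.random.SeedSequence([seed, 2, counter]))
            counter += 1
            aid = f"{qid}a{ai:03d}"
            a_cls = a_classes[int(sub_a.choice(len(a_classes), p=a_probs))]
            likes = _class_count(sub_a, cfg.engagement_model[a_cls])
            if a_cls == "AHE":
                n_high_a += 1
                if likes >= cfg.ahe_min_likes:
                    n_high_ok += 1
            m = float(cfg.style_match.get(a_cls, 0.5))
            base = sub_a.dirichlet(np.full(n_fc, cfg.style_conc))
            style_a = (1.0 - m) * base + m * style_q
            weights_a = class_weights.get(a_cls, ones)
            L = int(cfg.answer_len.sample(sub_a)[0])
            body_a = " ".join(draw_tokens(sub_a, L, None, topic, weights_a, style_a))
            posts.append(Post(aid, "answer", qid, "", body_a, like_count=likes))
            a_rows.append(
                {"id": aid, "parent_id": qid, "cls": a_cls, "m": m,
                 **{f"style_{c}": style_a[j] for j, c in enumerate(fcats)}}
            )
    if n_high_a and n_high_ok / n_high_a < 0.9:
        warnings.warn(
            f"engagement model gives only {n_high_ok}/{n_high_a} planted-high "
            f"answers like counts >= {cfg.ahe_min_likes}; partition support is weak",
            stacklevel=2,
        )
    truth = GroundTruth(
        pd.DataFrame(q_rows), pd.DataFrame(a_rows), phi, word_ids, cfg
    )
    return Corpus(posts), truth
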
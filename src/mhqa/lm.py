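"""Language-model cross-entropy divergence between corpus classes.

To quantify how differently two post classes A and B use language, a model
is trained on A's training split and evaluated on held-out text from both
classes.  The entropy difference

    E_{A,B} = CE(LM_A, B_test) - CE(LM_A, A_test)

is positive when B is harder for A's model than A's own held-out text, i.e.
when the classes diverge linguistically; E(A, A) = 0 by construction.

The reference backend is a deterministic interpolated additive-smoothing
n-gram model (default order 3, smoothing 0.1): order-k probabilities back
off recursively to shorter contexts,

    P_k(w|h) = (c(h, w) + delta * P_{k-1}(w|h[1:])) / (c(h) + delta),

with a uniform distribution over vocabulary + UNK at the base, so every
sequence over vocabulary + UNK has positive probability whenever delta > 0.
An optional recurrent backend mirrors the published training protocol
(lr 1e-3, dropout 0.4, SGD, cross-entropy loss, 50 epochs) and requires the
optional torch dependency.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SplitCorpus",
    "LmConfig",
    "NGramLM",
    "EntropyResult",
    "split_corpus",
    "train_lm",
    "cross_entropy",
    "entropy_difference",
    "paired_divergence",
]

Doc = Sequence[str]

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"


@dataclass
class SplitCorpus:
    """Train/validation/test document split (default ratios 8:1:1)."""

    train: list[Doc]
    valid: list[Doc]
    test: list[Doc]
    ratios: tuple[int, int, int]
    seed: int


@dataclass
class LmConfig:
    backend: str = "ngram"  # "ngram" | "recurrent"
    order: int = 3
    smoothing: float = 0.1
    include_eos: bool = True
    pooled_dictionary: bool = False  # fidelity flag: build vocab on train+test
    # recurrent-backend hyperparameters (published protocol)
    learning_rate: float = 1e-3
    dropout: float = 0.4
    epochs: int = 50


def split_corpus(
    docs: Sequence[Doc], ratios: tuple[int, int, int] = (8, 1, 1), seed: int = 0
) -> SplitCorpus:
    """Uniform shuffle then split; valid/test get the floor of their share,
    the remainder goes to train."""
    n = len(docs)
    if n < 3:
        raise ValueError("need at least 3 documents to split")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_valid = int(n * ratios[1] // total)
    n_test = int(n * ratios[2] // total)
    n_valid, n_test = max(n_valid, 1), max(n_test, 1)
    test_idx = order[:n_test]
    valid_idx = order[n_test : n_test + n_valid]
    train_idx = order[n_test + n_valid :]
    pick = lambda idx: [docs[i] for i in idx]
    return SplitCorpus(pick(train_idx), pick(valid_idx), pick(test_idx), ratios, seed)


class NGramLM:
    """Interpolated additive-smoothing n-gram model.

    Deterministic given the training documents; ``seed`` is recorded for
    provenance only.  Tokens outside the dictionary map to UNK at scoring
    time.  With ``include_eos`` each document also predicts an end-of-text
    symbol, making P a proper distribution over variable-length documents.
    """

    def __init__(
        self,
        order: int = 3,
        smoothing: float = 0.1,
        include_eos: bool = True,
        seed: int = 0,
    ):
        if order < 1:
            raise ValueError("order must be >= 1")
        if smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        self.order = order
        self.smoothing = smoothing
        self.include_eos = include_eos
        self.seed = seed
        self.vocab: frozenset[str] = frozenset()
        # context-length k (0..order-1): {context tuple: Counter of next word}
        self._counts: list[dict[tuple[str, ...], Counter]] = [
            {} for _ in range(order)
        ]
        self._totals: list[dict[tuple[str, ...], int]] = [{} for _ in range(order)]
        self._uniform: float = 0.0

    def fit(self, docs: Sequence[Doc], extra_vocab: Sequence[str] = ()) -> "NGramLM":
        vocab = {w for doc in docs for w in doc}
        vocab.update(extra_vocab)
        if not vocab:
            raise ValueError("empty training vocabulary")
        self.vocab = frozenset(vocab)
        n_events = len(self.vocab) + 1  # + UNK
        if self.include_eos:
            n_events += 1  # + EOS
        self._uniform = 1.0 / n_events
        for doc in docs:
            toks = [w if w in self.vocab else UNK for w in doc]
            if self.include_eos:
                toks = toks + [EOS]
            padded = [BOS] * (self.order - 1) + toks
            for pos in range(self.order - 1, len(padded)):
                w = padded[pos]
                for k in range(self.order):
                    ctx = tuple(padded[pos - k : pos])
                    self._counts[k].setdefault(ctx, Counter())[w] += 1
                    self._totals[k][ctx] = self._totals[k].get(ctx, 0) + 1
        return self

    @classmethod
    def uniform(cls, vocab: Sequence[str]) -> "NGramLM":
        """A degenerate model assigning 1/|vocab| to every token.

        Used as an analytic reference: per-token cross-entropy is ln|vocab|
        on any document, so every entropy difference is exactly zero.
        """
        lm = cls(order=1, smoothing=0.0, include_eos=False)
        lm.vocab = frozenset(vocab)
        lm._uniform = 1.0 / len(lm.vocab)
        lm._is_uniform = True
        return lm

    def prob(self, word: str, context: Sequence[str] = ()) -> float:
        """P(word | context) with recursive interpolation down to uniform."""
        if getattr(self, "_is_uniform", False):
            return self._uniform
        if word not in self.vocab and word not in (EOS,):
            word = UNK
        ctx = tuple(context)[-(self.order - 1) :] if self.order > 1 else ()
        return self._prob_k(word, ctx, len(ctx))

    def _prob_k(self, word: str, ctx: tuple[str, ...], k: int) -> float:
        if k == 0:
            total = self._totals[0].get((), 0)
            c = self._counts[0].get((), Counter()).get(word, 0)
            if self.smoothing == 0.0:
                return c / total if total else self._uniform
            # interpolate the unigram with the uniform base distribution
            return (c + self.smoothing * self._uniform) / (total + self.smoothing)
        lower = self._prob_k(word, ctx[1:], k - 1)
        total = self._totals[k].get(ctx, 0)
        c = self._counts[k].get(ctx, Counter()).get(word, 0)
        if total == 0 and self.smoothing == 0.0:
            return lower
        return (c + self.smoothing * lower) / (total + self.smoothing)

    def logprob_doc(self, doc: Doc) -> float:
        """Natural-log probability of a document (sum over token events)."""
        toks = list(doc)
        if self.include_eos and not getattr(self, "_is_uniform", False):
            toks = toks + [EOS]
        padded = [BOS] * (self.order - 1) + [
            w if (w in self.vocab or w == EOS) else UNK for w in toks
        ]
        logp = 0.0
        for pos in range(self.order - 1, len(padded)):
            ctx = tuple(padded[pos - (self.order - 1) : pos])
            p = (
                self._uniform
                if getattr(self, "_is_uniform", False)
                else self._prob_k(padded[pos], ctx, len(ctx))
            )
            if p <= 0.0:
                raise ValueError(
                    "zero-probability event; use smoothing > 0 for open-vocabulary text"
                )
            logp += math.log(p)
        return logp

    def n_events(self, doc: Doc) -> int:
        extra = 1 if (self.include_eos and not getattr(self, "_is_uniform", False)) else 0
        return len(doc) + extra


@dataclass
class EntropyResult:
    """Directed divergence of class B from class A under A's language model."""

    model_class: str  # e.g. "LMQHE"
    h_own: float  # cross-entropy on A's own test split
    h_other: float  # cross-entropy on B's test split
    entropy_difference: float  # E = h_other - h_own
    normalization: str  # "per_token" | "per_document"
    topic: object = None
    backend: str = "ngram"
    seed: int = 0


def train_lm(
    train: Sequence[Doc], cfg: LmConfig | None = None, seed: int = 0,
    extra_vocab: Sequence[str] = (),
) -> NGramLM:
    """Train a language model on a document list.

    ``extra_vocab`` supports the pooled-dictionary fidelity mode in which the
    dictionary covers all words of the topic (train and test pooled), as the
    published protocol describes; the default dictionary is train-only, the
    leak-free choice.
    """
    cfg = cfg or LmConfig()
    if not train:
        raise ValueError("empty training set")
    if cfg.backend == "ngram":
        lm = NGramLM(cfg.order, cfg.smoothing, cfg.include_eos, seed)
        return lm.fit(train, extra_vocab=extra_vocab)
    if cfg.backend == "recurrent":
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the recurrent backend requires the optional torch dependency "
                "(pip install mhqa[recurrent]); the ngram backend is the "
                "deterministic reference"
            ) from exc
        raise NotImplementedError(
            "recurrent backend: train an LSTM with lr=1e-3, dropout=0.4, SGD, "
            "cross-entropy loss, 50 epochs"
        )
    raise ValueError(f"unknown LM backend {cfg.backend!r}")


def cross_entropy(lm: NGramLM, docs: Sequence[Doc], normalization: str = "per_token") -> float:
    """Cross-entropy (nats) of documents under a model.

    per_token: -(sum log P) / (number of predicted tokens); per_document:
    -(1/|docs|) * sum_d log P(d).  Per-document conflates length with style
    and is provided for strict fidelity with the published formula.
    """
    if not docs:
        raise ValueError("empty document set")
    logps = [lm.logprob_doc(d) for d in docs]
    if normalization == "per_token":
        n = sum(lm.n_events(d) for d in docs)
        if n == 0:
            raise ValueError("zero tokens in document set")
        return -sum(logps) / n
    if normalization == "per_document":
        return -sum(logps) / len(docs)
    raise ValueError(f"unknown normalization {normalization!r}")


def entropy_difference(
    lm_A: NGramLM,
    A_test: Sequence[Doc],
    B_test: Sequence[Doc],
    normalization: str = "per_token",
    model_class: str = "LM_A",
    topic: object = None,
) -> EntropyResult:
    """E = CE(lm_A, B_test) - CE(lm_A, A_test)."""
    h_own = cross_entropy(lm_A, A_test, normalization)
    h_other = cross_entropy(lm_A, B_test, normalization)
    return EntropyResult(
        model_class, h_own, h_other, h_other - h_own, normalization, topic,
        "ngram", lm_A.seed,
    )


def paired_divergence(
    set_A: Sequence[Doc],
    set_B: Sequence[Doc],
    cfg: LmConfig | None = None,
    seed: int = 0,
    labels: tuple[str, str] = ("LM_A", "LM_B"),
    normalization: str = "per_token",
    topic: object = None,
) -> tuple[EntropyResult, EntropyResult]:
    """Both directed entropy differences between two document classes.

    Each class is split 8:1:1 (deterministic sub-seeds derived from ``seed``),
    a model is trained on each training split, and E is computed in both
    directions.  With identical inputs and the same seed both differences are
    exactly zero.
    """
    cfg = cfg or LmConfig()
    seed_a = int(np.random.SeedSequence([seed, 0]).generate_state(1)[0] % (2**31))
    seed_b = int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31))
    split_a = split_corpus(set_A, seed=seed_a)
    split_b = split_corpus(set_B, seed=seed_a if set_A is set_B or list(set_A) == list(set_B) else seed_b)
    pooled_a = [w for d in split_a.test for w in d] if cfg.pooled_dictionary else ()
    pooled_b = [w for d in split_b.test for w in d] if cfg.pooled_dictionary else ()
    lm_a = train_lm(split_a.train, cfg, seed=seed_a, extra_vocab=list(pooled_a) + list(pooled_b))
    lm_b = train_lm(split_b.train, cfg, seed=seed_b, extra_vocab=list(pooled_a) + list(pooled_b))
    res_a = entropy_difference(
        lm_a, split_a.test, split_b.test, normalization, labels[0], topic
    )
    res_b = entropy_difference(
        lm_b, split_b.test, split_a.test, normalization, labels[1], topic
    )
    return res_a, res_b
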
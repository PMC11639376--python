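"""Topic modeling: vocabulary, bag-of-words/TF-IDF, collapsed-Gibbs LDA,
perplexity and UMass coherence for model selection, relevance-ranked
keywords, and document topic assignment.

LDA treats each document as a mixture over K latent topics, each topic a
distribution over the vocabulary.  Inference is collapsed Gibbs sampling with
symmetric Dirichlet priors alpha (doc-topic) and beta (topic-word); point
estimates are the standard smoothed frequency ratios

    phi_kw   = (n_kw + beta) / (n_k + V*beta)
    theta_dk = (n_dk + alpha) / (n_d + K*alpha)

Keyword ranking uses the lambda-relevance score familiar from topic-model
visualization: relevance(w) = lam*log phi_kw + (1-lam)*log(phi_kw / p(w)).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "BowCorpus",
    "LdaModel",
    "ModelSelectionReport",
    "build_vocab",
    "to_bow",
    "tfidf_weights",
    "fit_lda",
    "perplexity",
    "coherence_umass",
    "select_k",
    "top_keywords",
    "assign_topics",
]


@dataclass
class Vocabulary:
    """Dense word<->id maps, ordered by first occurrence in the corpus."""

    word2id: dict[str, int]
    doc_freq: dict[str, int]
    min_count: int
    stopwords: frozenset[str]
    id2word: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id2word:
            self.id2word = [""] * len(self.word2id)
            for w, i in self.word2id.items():
                self.id2word[i] = w

    def __len__(self) -> int:
        return len(self.word2id)

    def __contains__(self, word: str) -> bool:
        return word in self.word2id


@dataclass
class BowCorpus:
    """Sparse per-document (word id, weight) vectors."""

    docs: list[list[tuple[int, float]]]
    n_words: int
    mode: str = "count"  # "count" | "tfidf"

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    def doc_lengths(self) -> np.ndarray:
        return np.array([sum(w for _, w in d) for d in self.docs])

    def total_tokens(self) -> float:
        return float(self.doc_lengths().sum())


@dataclass
class LdaModel:
    K: int
    alpha: float
    beta: float
    phi: np.ndarray  # (K, V) topic-word, rows sum to 1
    theta: np.ndarray  # (D, K) doc-topic, rows sum to 1
    assignments: np.ndarray | None = None  # token-topic state
    n_iters: int = 0
    seed: int = 0
    vocab: Vocabulary | None = None


@dataclass
class ModelSelectionReport:
    grid: list[int]
    perplexities: dict[int, float]
    coherences: dict[int, float]
    chosen_k: int
    trace: list[str]
    models: dict[int, LdaModel] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.grid,
                "perplexity": [self.perplexities[k] for k in self.grid],
                "coherence": [self.coherences[k] for k in self.grid],
                "chosen": [k == self.chosen_k for k in self.grid],
            }
        )


def build_vocab(
    docs: Iterable[Sequence[str]],
    min_count: int = 1,
    stopwords: Iterable[str] = (),
) -> Vocabulary:
    """Vocabulary of words with corpus frequency >= min_count, stopwords
    removed, ids ordered by first occurrence."""
    stop = frozenset(stopwords)
    counts: dict[str, int] = {}
    dfreq: dict[str, int] = {}
    order: list[str] = []
    for doc in docs:
        seen = set()
        for w in doc:
            if w in stop:
                continue
            if w not in counts:
                counts[w] = 0
                order.append(w)
            counts[w] += 1
            if w not in seen:
                dfreq[w] = dfreq.get(w, 0) + 1
                seen.add(w)
    kept = [w for w in order if counts[w] >= min_count]
    if not kept:
        raise ValueError("empty vocabulary after min_count/stopword filtering")
    return Vocabulary(
        {w: i for i, w in enumerate(kept)},
        {w: dfreq[w] for w in kept},
        min_count,
        stop,
    )


def to_bow(docs: Iterable[Sequence[str]], vocab: Vocabulary) -> BowCorpus:
    """Count vectors; out-of-vocabulary tokens are dropped."""
    out: list[list[tuple[int, float]]] = []
    n_empty = 0
    for doc in docs:
        counts: dict[int, int] = {}
        for w in doc:
            i = vocab.word2id.get(w)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        if not counts:
            n_empty += 1
        out.append(sorted((i, float(c)) for i, c in counts.items()))
    if n_empty:
        warnings.warn(
            f"{n_empty} document(s) became empty after vocabulary mapping",
            stacklevel=2,
        )
    return BowCorpus(out, len(vocab), "count")


def tfidf_weights(bow: BowCorpus) -> BowCorpus:
    """TF-IDF reweighting: weight(d,w) = tf * log2(D / df(w)), L2-normalized."""
    if bow.mode != "count":
        raise ValueError("tfidf_weights expects a count-mode corpus")
    D = bow.n_docs
    df = np.zeros(bow.n_words)
    for doc in bow.docs:
        for i, _ in doc:
            df[i] += 1
    out: list[list[tuple[int, float]]] = []
    for doc in bow.docs:
        vec = [(i, tf * math.log2(D / df[i])) for i, tf in doc]
        norm = math.sqrt(sum(w * w for _, w in vec))
        if norm > 0:
            vec = [(i, w / norm) for i, w in vec]
        out.append(vec)
    return BowCorpus(out, bow.n_words, "tfidf")


def _flatten(bow: BowCorpus) -> tuple[np.ndarray, np.ndarray]:
    words, docs = [], []
    for d, doc in enumerate(bow.docs):
        for i, c in doc:
            n = int(round(c))
            words.extend([i] * n)
            docs.extend([d] * n)
    return (
        np.asarray(words, dtype=np.int32),
        np.asarray(docs, dtype=np.int32),
    )


def fit_lda(
    bow: BowCorpus,
    K: int,
    iters: int = 40,
    alpha: float | None = None,
    beta: float = 0.01,
    seed: int = 0,
    allow_tfidf: bool = False,
) -> LdaModel:
    """Fit LDA by collapsed Gibbs sampling; deterministic per seed.

    LDA is defined on word counts; TF-IDF-weighted input is accepted only
    with ``allow_tfidf=True``, in which case weights are rounded to
    pseudo-counts (weights < 0.5 vanish) and a loud log message records the
    statistically non-standard path.
    """
    if K < 1 or iters < 1:
        raise ValueError("K and iters must be >= 1")
    if bow.mode != "count":
        if not allow_tfidf:
            raise ValueError(
                "fit_lda expects count-mode input; pass allow_tfidf=True to "
                "round TF-IDF weights to pseudo-counts"
            )
        scale = max(
            (w for doc in bow.docs for _, w in doc), default=1.0
        )
        rescaled = [
            [(i, round(10.0 * w / scale)) for i, w in doc] for doc in bow.docs
        ]
        bow = BowCorpus(
            [[(i, float(c)) for i, c in doc if c > 0] for doc in rescaled],
            bow.n_words,
            "count",
        )
        logger.warning(
            "fit_lda: TF-IDF weights rounded to pseudo-counts (x10/max scale); "
            "LDA on TF-IDF is non-standard and provided for fidelity only"
        )
    if alpha is None:
        alpha = 50.0 / K
    token_word, token_doc = _flatten(bow)
    if token_word.size == 0:
        raise ValueError("cannot fit LDA on an empty corpus")
    from ._gibbs import gibbs_sample

    D, V = bow.n_docs, bow.n_words
    z, n_wk, n_dk, n_k = gibbs_sample(
        token_word, token_doc, K, V, D, float(alpha), float(beta), iters, int(seed) % (2**31)
    )
    phi = (n_wk.T + beta) / (n_k[:, None] + V * beta)
    n_d = n_dk.sum(axis=1)
    theta = (n_dk + alpha) / (n_d[:, None] + K * alpha)
    return LdaModel(K, float(alpha), float(beta), phi, theta, z, iters, seed, None)


def perplexity(model: LdaModel, bow: BowCorpus) -> float:
    """exp(- sum_d sum_w n_dw log p(w|d) / N) with p(w|d) = sum_k theta_dk phi_kw."""
    if bow.n_docs != model.theta.shape[0]:
        raise ValueError("bow corpus and model have different document counts")
    loglik = 0.0
    n_tokens = 0.0
    for d, doc in enumerate(bow.docs):
        if not doc:
            continue
        theta_d = model.theta[d]
        for i, c in doc:
            p = float(theta_d @ model.phi[:, i])
            loglik += c * math.log(p)
            n_tokens += c
    if n_tokens == 0:
        raise ValueError("cannot compute perplexity on zero tokens")
    return math.exp(-loglik / n_tokens)


def coherence_umass(model: LdaModel, bow: BowCorpus, topn: int = 10) -> float:
    """UMass coherence averaged over topics.

    For each topic's topn words (ranked by phi, ties to the lower word id),
    sums log((D(w_i, w_j) + 1) / D(w_j)) over ordered pairs i < j, where D
    counts documents containing the word(s).  Higher (closer to 0) is more
    coherent.
    """
    V = model.phi.shape[1]
    if topn > V:
        warnings.warn(f"topn={topn} exceeds vocabulary size {V}; clamped", stacklevel=2)
        topn = V
    doc_sets: list[set[int]] = [set(i for i, _ in doc) for doc in bow.docs]
    doc_freq = np.zeros(V)
    for s in doc_sets:
        for i in s:
            doc_freq[i] += 1
    scores = []
    for k in range(model.K):
        order = np.lexsort((np.arange(V), -model.phi[k]))[:topn]
        total = 0.0
        for a in range(1, topn):
            wi = order[a]
            for b in range(a):
                wj = order[b]
                co = sum(1 for s in doc_sets if wi in s and wj in s)
                if doc_freq[wj] > 0:
                    total += math.log((co + 1) / doc_freq[wj])
        scores.append(total)
    return float(np.mean(scores))


def select_k(
    bow: BowCorpus,
    k_grid: Sequence[int],
    iters: int = 40,
    alpha: float | None = None,
    beta: float = 0.01,
    seed: int = 0,
    topn: int = 10,
) -> ModelSelectionReport:
    """Fit one model per K; choose the K maximizing coherence.

    Perplexity is reported alongside for diagnosis (the published workflow
    weighed both "consistency" and perplexity by eye; this is the automated
    surrogate).  Ties break to the smaller K.
    """
    if not k_grid:
        raise ValueError("empty K grid")
    perps: dict[int, float] = {}
    cohs: dict[int, float] = {}
    models: dict[int, LdaModel] = {}
    trace: list[str] = []
    for k in k_grid:
        m = fit_lda(bow, k, iters=iters, alpha=alpha, beta=beta, seed=seed)
        perps[k] = perplexity(m, bow)
        cohs[k] = coherence_umass(m, bow, topn=topn)
        models[k] = m
        trace.append(f"K={k}: perplexity={perps[k]:.4f} coherence={cohs[k]:.4f}")
    chosen = max(sorted(k_grid), key=lambda k: (cohs[k], -k))
    trace.append(f"chosen K={chosen} (max coherence)")
    return ModelSelectionReport(list(k_grid), perps, cohs, chosen, trace, models)


def top_keywords(
    model: LdaModel,
    topic: int,
    n: int = 30,
    lam: float = 0.6,
    bow: BowCorpus | None = None,
    p_w: np.ndarray | None = None,
) -> list[int]:
    """Top-n word ids of a topic by lambda-relevance.

    relevance(w) = lam*log(phi_kw) + (1-lam)*log(phi_kw / p(w)), with p(w)
    the corpus marginal word frequency (from ``bow`` or given directly).
    lam=1 reduces to ranking by phi.  Ties break to the lower word id.
    """
    if not 0 <= topic < model.K:
        raise ValueError(f"topic {topic} out of range for K={model.K}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    V = model.phi.shape[1]
    if p_w is None:
        if bow is None:
            p_w = np.full(V, 1.0 / V)
        else:
            counts = np.zeros(V)
            for doc in bow.docs:
                for i, c in doc:
                    counts[i] += c
            total = counts.sum()
            p_w = counts / total if total > 0 else np.full(V, 1.0 / V)
    phi_k = model.phi[topic]
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi_k)
        lift = np.where(p_w > 0, np.log(np.where(p_w > 0, phi_k / p_w, 1.0)), -np.inf)
    relevance = lam * log_phi + (1.0 - lam) * lift
    order = np.lexsort((np.arange(V), -relevance))
    return [int(i) for i in order[:n]]


UNASSIGNED = -1


def assign_topics(model: LdaModel, bow: BowCorpus) -> np.ndarray:
    """Hard topic label per document: argmax_k theta_dk; ties to lowest k.

    Documents that are empty after vocabulary mapping get the sentinel -1.
    """
    if bow.n_docs != model.theta.shape[0]:
        raise ValueError("bow corpus and model have different document counts")
    labels = np.argmax(model.theta, axis=1).astype(int)
    for d, doc in enumerate(bow.docs):
        if not doc:
            labels[d] = UNASSIGNED
    return labels
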
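"""Vocabulary/BoW, TF-IDF, Gibbs LDA, perplexity, coherence, keywords."""

import math

import numpy as np
import pytest

from mhqa import (
    BowCorpus,
    LdaModel,
    assign_topics,
    build_vocab,
    coherence_umass,
    fit_lda,
    generate_corpus,
    perplexity,
    select_k,
    tfidf_weights,
    to_bow,
    tokenize,
    top_keywords,
)
from mhqa.synth import LengthSpec, SynthConfig


def lda_corpus(n_docs, seed, n_topics=4, vocab_size=400, doc_len=60):
    """Planted pure-LDA corpus (no function-word noise)."""
    cfg = SynthConfig(
        n_questions=n_docs,
        n_topics=n_topics,
        vocab_size=vocab_size,
        n_function_words=16,
        function_word_rate=0.0,
        question_len=LengthSpec(doc_len, float("inf")),
        title_len=LengthSpec(0),
        answers_per_question=LengthSpec(0),
    )
    corpus, truth = generate_corpus(cfg, seed=seed)
    docs = [tokenize(q.body) for q in corpus.questions()]
    return docs, truth


def matched_tv(model, truth, vocab):
    """Greedy-match planted to estimated topics; mean total-variation."""
    K = truth.topic_word.shape[0]
    planted = np.zeros((K, len(vocab)))
    inv = {i: w for w, i in truth.word_ids.items()}
    for j in range(truth.topic_word.shape[1]):
        w = inv[j]
        if w in vocab.word2id:
            planted[:, vocab.word2id[w]] = truth.topic_word[:, j]
    planted /= planted.sum(axis=1, keepdims=True)
    tv = 0.5 * np.abs(planted[:, None, :] - model.phi[None, :, :]).sum(axis=2)
    used, tvs, match = set(), [], {}
    for k in range(K):
        j = min((j for j in range(model.K) if j not in used), key=lambda j: tv[k, j])
        used.add(j)
        tvs.append(tv[k, j])
        match[k] = j
    return float(np.mean(tvs)), match


class TestVocabBow:
    def test_min_count(self):
        v = build_vocab([["a", "a", "b"]], min_count=2)
        assert set(v.word2id) == {"a"}

    def test_stopwords(self):
        v = build_vocab([["a", "b"]], stopwords={"a"})
        assert set(v.word2id) == {"b"}

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            build_vocab([["a"]], min_count=5)

    def test_ids_ordered_by_first_occurrence(self):
        v = build_vocab([["c", "a"], ["b", "a"]])
        assert v.word2id == {"c": 0, "a": 1, "b": 2}

    def test_vocab_size_matches_brute_force(self, rng):
        words = [f"w{i}" for i in range(30)]
        docs = [[words[i] for i in rng.integers(0, 30, 50)] for _ in range(10)]
        v = build_vocab(docs, min_count=3)
        from collections import Counter

        counts = Counter(t for d in docs for t in d)
        assert len(v) == sum(1 for c in counts.values() if c >= 3)

    def test_to_bow_counts(self):
        v = build_vocab([["a", "a", "b"]])
        bow = to_bow([["a", "a", "b"]], v)
        assert bow.docs == [[(0, 2.0), (1, 1.0)]]

    def test_all_oov_doc_retained_with_warning(self):
        v = build_vocab([["a"]])
        with pytest.warns(UserWarning, match="empty"):
            bow = to_bow([["a"], ["zzz"]], v)
        assert bow.docs[1] == []

    def test_bow_totals_equal_tokens_minus_oov(self, rng):
        docs, _ = lda_corpus(20, seed=3)
        v = build_vocab(docs, min_count=2)
        bow = to_bow(docs, v)
        expected = sum(1 for d in docs for t in d if t in v.word2id)
        assert bow.total_tokens() == expected


class TestTfidf:
    def test_word_in_every_doc_weighs_zero(self):
        docs = [["a", "b"], ["a", "c"], ["a", "d"]]
        v = build_vocab(docs)
        w = tfidf_weights(to_bow(docs, v))
        a = v.word2id["a"]
        for doc in w.docs:
            assert dict(doc).get(a, 0.0) == pytest.approx(0.0)

    def test_single_doc_corpus_degenerates_to_zero(self):
        docs = [["a", "b", "b"]]
        w = tfidf_weights(to_bow(docs, build_vocab(docs)))
        assert all(weight == 0.0 for doc in w.docs for _, weight in doc)

    def test_three_doc_fixture_matches_hand_formula(self):
        docs = [["a", "a", "b"], ["a", "c"], ["c", "c", "c", "b"]]
        v = build_vocab(docs)
        w = tfidf_weights(to_bow(docs, v))
        # doc 0: tf(a)=2 idf(a)=log2(3/2), tf(b)=1 idf(b)=log2(3/2)
        raw = {"a": 2 * math.log2(3 / 2), "b": 1 * math.log2(3 / 2)}
        norm = math.sqrt(sum(x * x for x in raw.values()))
        expected = {v.word2id[k]: val / norm for k, val in raw.items()}
        assert dict(w.docs[0]) == pytest.approx(expected)
        assert w.mode == "tfidf"


class TestFitLda:
    def test_k1_closed_form(self):
        docs = [["a", "a", "b"], ["b", "c"]]
        v = build_vocab(docs)
        bow = to_bow(docs, v)
        m = fit_lda(bow, K=1, iters=5, alpha=0.1, beta=0.01, seed=0)
        assert np.allclose(m.theta, 1.0)
        N, V = 5, 3
        for w, n_w in (("a", 2), ("b", 2), ("c", 1)):
            expected = (n_w + 0.01) / (N + V * 0.01)
            assert m.phi[0, v.word2id[w]] == pytest.approx(expected)

    def test_deterministic_per_seed(self):
        docs, _ = lda_corpus(50, seed=1)
        bow = to_bow(docs, build_vocab(docs))
        m1 = fit_lda(bow, 3, iters=20, seed=42)
        m2 = fit_lda(bow, 3, iters=20, seed=42)
        assert np.array_equal(m1.phi, m2.phi)
        assert np.array_equal(m1.theta, m2.theta)

    def test_rows_are_distributions(self):
        docs, _ = lda_corpus(50, seed=2)
        bow = to_bow(docs, build_vocab(docs))
        m = fit_lda(bow, 4, iters=10, seed=0)
        np.testing.assert_allclose(m.phi.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(m.theta.sum(axis=1), 1.0, atol=1e-9)

    def test_tfidf_input_requires_flag(self):
        docs = [["a", "b"], ["a", "c"], ["b", "c"]]
        w = tfidf_weights(to_bow(docs, build_vocab(docs)))
        with pytest.raises(ValueError, match="allow_tfidf"):
            fit_lda(w, 2, iters=2)
        m = fit_lda(w, 2, iters=2, allow_tfidf=True, seed=0)
        assert m.K == 2

    def test_empty_corpus_rejected(self):
        bow = BowCorpus([[], []], 3)
        with pytest.raises(ValueError, match="empty"):
            fit_lda(bow, 2, iters=2)

    def test_planted_topic_recovery(self):
        # single Gibbs chains can stick in a merged-topic mode on small
        # corpora; at 800 docs recovery is robust across chain seeds
        docs, truth = lda_corpus(800, seed=5)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        m = fit_lda(bow, 4, iters=200, alpha=0.1, beta=0.01, seed=17)
        tv, _ = matched_tv(m, truth, vocab)
        assert tv <= 0.25

    def test_recovery_improves_with_corpus_size(self):
        tvs = {}
        for n in (100, 800):
            docs, truth = lda_corpus(n, seed=23)
            vocab = build_vocab(docs)
            m = fit_lda(to_bow(docs, vocab), 4, iters=150, alpha=0.1, beta=0.01, seed=23)
            tvs[n], _ = matched_tv(m, truth, vocab)
        assert tvs[800] < tvs[100]

    def test_training_perplexity_decreases_over_sweeps(self):
        docs, _ = lda_corpus(150, seed=31)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        early, late = [], []
        for seed in range(5):
            m1 = fit_lda(bow, 4, iters=1, alpha=0.1, beta=0.01, seed=seed)
            m2 = fit_lda(bow, 4, iters=100, alpha=0.1, beta=0.01, seed=seed)
            early.append(perplexity(m1, bow))
            late.append(perplexity(m2, bow))
        assert np.median(late) < np.median(early)


class TestPerplexity:
    def test_uniform_model_equals_vocab_size(self):
        V, D, K = 10, 4, 3
        model = LdaModel(K, 0.1, 0.01, np.full((K, V), 1 / V), np.full((D, K), 1 / K))
        docs = [[(i % V, 2.0)] for i in range(D)]
        assert perplexity(model, BowCorpus(docs, V)) == pytest.approx(V)

    def test_deterministic_single_word_limit(self):
        # K=1, one-word corpus, beta -> 0: perplexity -> 1
        docs = [["a", "a", "a"]]
        bow = to_bow(docs, build_vocab(docs))
        m = fit_lda(bow, 1, iters=2, alpha=0.1, beta=1e-12, seed=0)
        assert perplexity(m, bow) == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_formula(self):
        docs, _ = lda_corpus(30, seed=3)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        m = fit_lda(bow, 3, iters=20, seed=1)
        loglik = n = 0.0
        for d, doc in enumerate(bow.docs):
            for i, c in doc:
                loglik += c * math.log(float(m.theta[d] @ m.phi[:, i]))
                n += c
        assert perplexity(m, bow) == pytest.approx(math.exp(-loglik / n))

    def test_zero_tokens_rejected(self):
        m = LdaModel(1, 0.1, 0.01, np.ones((1, 2)) / 2, np.ones((2, 1)))
        with pytest.raises(ValueError):
            perplexity(m, BowCorpus([[], []], 2))


class TestCoherence:
    def make_model(self, phi):
        phi = np.asarray(phi, dtype=float)
        D = 1
        return LdaModel(phi.shape[0], 0.1, 0.01, phi, np.ones((D, phi.shape[0])) / phi.shape[0])

    def test_all_cooccurring_pair_closed_form(self):
        # both top words in all 10 docs: one pair, log(11/10)
        model = self.make_model([[0.6, 0.4]])
        docs = [[(0, 1.0), (1, 1.0)] for _ in range(10)]
        bow = BowCorpus(docs, 2)
        bow_model = self.make_model([[0.6, 0.4]])
        score = coherence_umass(bow_model, bow, topn=2)
        assert score == pytest.approx(math.log(11 / 10))

    def test_never_cooccurring_pair(self):
        model = self.make_model([[0.6, 0.4]])
        docs = [[(0, 1.0)]] * 4 + [[(1, 1.0)]] * 6
        score = coherence_umass(model, BowCorpus(docs, 2), topn=2)
        # D(w_j)=D(word 0)=4 (higher-phi word), co-occurrence 0 -> log(1/4)
        assert score == pytest.approx(math.log(1 / 4))

    def test_matches_brute_force(self, rng):
        docs, _ = lda_corpus(40, seed=9)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        m = fit_lda(bow, 3, iters=20, seed=2)
        topn = 5
        doc_sets = [set(i for i, _ in d) for d in bow.docs]
        expected = []
        for k in range(3):
            order = sorted(range(len(vocab)), key=lambda i: (-m.phi[k, i], i))[:topn]
            s = 0.0
            for a in range(1, topn):
                for b in range(a):
                    wi, wj = order[a], order[b]
                    co = sum(1 for ds in doc_sets if wi in ds and wj in ds)
                    dj = sum(1 for ds in doc_sets if wj in ds)
                    s += math.log((co + 1) / dj)
            expected.append(s)
        assert coherence_umass(m, bow, topn=topn) == pytest.approx(np.mean(expected))

    def test_topn_clamped_with_warning(self):
        model = self.make_model([[0.6, 0.4]])
        bow = BowCorpus([[(0, 1.0), (1, 1.0)]], 2)
        with pytest.warns(UserWarning, match="clamped"):
            coherence_umass(model, bow, topn=99)


class TestSelectK:
    def test_singleton_grid(self):
        docs, _ = lda_corpus(40, seed=4)
        bow = to_bow(docs, build_vocab(docs))
        report = select_k(bow, [4], iters=10, seed=0)
        assert report.chosen_k == 4
        assert report.to_frame()["chosen"].sum() == 1

    def test_deterministic(self):
        docs, _ = lda_corpus(40, seed=4)
        bow = to_bow(docs, build_vocab(docs))
        r1 = select_k(bow, [2, 3], iters=10, seed=7)
        r2 = select_k(bow, [2, 3], iters=10, seed=7)
        assert r1.chosen_k == r2.chosen_k
        assert r1.perplexities == r2.perplexities

    def test_prefers_planted_k(self):
        # planted K=4: coherence should rank K=4 best in most seeds
        wins = 0
        for seed in range(10):
            docs, _ = lda_corpus(150, seed=100 + seed)
            bow = to_bow(docs, build_vocab(docs, min_count=2))
            report = select_k(bow, [2, 4, 8], iters=60, alpha=0.1, seed=seed)
            wins += report.chosen_k == 4
        assert wins >= 8


class TestKeywordsAssign:
    def test_lam_one_equals_phi_ranking(self):
        docs, _ = lda_corpus(40, seed=6)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        m = fit_lda(bow, 3, iters=15, seed=3)
        ids = top_keywords(m, 0, n=10, lam=1.0, bow=bow)
        expected = sorted(range(len(vocab)), key=lambda i: (-m.phi[0, i], i))[:10]
        assert ids == expected

    def test_point_mass_topic_ranks_its_word_first(self):
        phi = np.array([[0.98, 0.01, 0.01], [0.1, 0.8, 0.1]])
        m = LdaModel(2, 0.1, 0.01, phi, np.ones((1, 2)) / 2)
        for lam in (0.0, 0.3, 0.6, 1.0):
            assert top_keywords(m, 0, n=1, lam=lam)[0] == 0

    def test_matches_brute_force_relevance(self):
        docs, _ = lda_corpus(40, seed=7)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        m = fit_lda(bow, 3, iters=15, seed=4)
        counts = np.zeros(len(vocab))
        for doc in bow.docs:
            for i, c in doc:
                counts[i] += c
        p_w = counts / counts.sum()
        lam = 0.6
        rel = lam * np.log(m.phi[1]) + (1 - lam) * np.log(m.phi[1] / p_w)
        expected = sorted(range(len(vocab)), key=lambda i: (-rel[i], i))[:30]
        assert top_keywords(m, 1, n=30, lam=lam, bow=bow) == expected

    def test_assign_k1_all_zero(self):
        docs = [["a", "b"], ["b"]]
        bow = to_bow(docs, build_vocab(docs))
        m = fit_lda(bow, 1, iters=2, seed=0)
        assert list(assign_topics(m, bow)) == [0, 0]

    def test_assign_empty_doc_sentinel(self):
        docs = [["a", "b"], ["b"]]
        v = build_vocab(docs)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bow = to_bow([["a"], ["zzz"]], v)
        m = fit_lda(BowCorpus([bow.docs[0], []], 2, "count"), 2, iters=2, seed=0)
        labels = assign_topics(m, BowCorpus([bow.docs[0], []], 2, "count"))
        assert labels[1] == -1

    def test_exclusive_word_doc_assigned_to_planted_topic(self):
        docs, truth = lda_corpus(300, seed=8)
        vocab = build_vocab(docs)
        bow = to_bow(docs, vocab)
        m = fit_lda(bow, 4, iters=150, alpha=0.1, beta=0.01, seed=5)
        tv, match = matched_tv(m, truth, vocab)
        labels = assign_topics(m, bow)
        topic_of = truth.topic_of()
        qids = sorted(topic_of)
        agree = np.mean(
            [match[topic_of[q]] == labels[i] for i, q in enumerate(qids)]
        )
        assert agree > 0.8
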
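"""Style matching: per-category scores, pair scores, aggregation, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhqa import bootstrap_ci, lsm_by_topic, lsm_category, lsm_pair
from mhqa.lexicon import DEFAULT_FUNCTION_CATEGORIES


class TestLsmCategory:
    @pytest.mark.parametrize(
        "pq,pa,expected,tol",
        [
            (5.0, 5.0, 1.0, 0),
            (4.0, 6.0, 1 - 2 / 10.0001, 1e-12),
            (5.0, 0.0, 1 - 5 / 5.0001, 1e-12),
            (0.0, 0.0, 1.0, 0),  # 1 - 0/.0001
        ],
    )
    def test_published_arithmetic(self, pq, pa, expected, tol):
        assert lsm_category(pq, pa) == pytest.approx(expected, abs=tol)

    @given(
        pq=st.floats(min_value=0, max_value=100),
        pa=st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_symmetric(self, pq, pa):
        s = lsm_category(pq, pa)
        assert 0.0 < s <= 1.0
        assert s == lsm_category(pa, pq)
        if abs(pq - pa) > 1e-9:  # strict inequality holds outside float noise
            assert s < 1.0


class TestLsmPair:
    def test_identical_sequences_score_one(self, tiny_lexicon):
        toks = ["f_conj", "sad", "f_prep", "x"]
        score = lsm_pair(toks, list(toks), tiny_lexicon)
        assert score.mean == pytest.approx(1.0)

    def test_symmetry(self, tiny_lexicon):
        q = ["f_conj", "f_conj", "x", "sad"]
        a = ["f_prep", "x", "x", "f_conj"]
        assert lsm_pair(q, a, tiny_lexicon).mean == pytest.approx(
            lsm_pair(a, q, tiny_lexicon).mean
        )

    def test_empty_sequence_rejected(self, tiny_lexicon):
        with pytest.raises(ValueError):
            lsm_pair([], ["x"], tiny_lexicon)

    def test_mean_over_exactly_eight_categories(self, tiny_lexicon):
        score = lsm_pair(["f_conj", "x"], ["x", "y"], tiny_lexicon)
        assert set(score.per_category) == set(DEFAULT_FUNCTION_CATEGORIES)
        assert score.mean == pytest.approx(np.mean(list(score.per_category.values())))

    def test_matches_brute_force_from_raw_counts(self, tiny_lexicon):
        q = ["f_conj", "f_conj", "f_ppron", "sad", "x", "y"]
        a = ["f_conj", "f_prep", "x", "x"]
        score = lsm_pair(q, a, tiny_lexicon)
        for cat in DEFAULT_FUNCTION_CATEGORIES:
            word = f"f_{cat}"
            pq = 100.0 * q.count(word) / len(q)
            pa = 100.0 * a.count(word) / len(a)
            expected = 1 - abs(pq - pa) / (pq + pa + 0.0001)
            assert score.per_category[cat] == pytest.approx(expected)

    def test_content_words_count_in_denominator(self, tiny_lexicon):
        # same function counts, different totals -> different proportions
        a = lsm_pair(["f_conj", "x"], ["f_conj", "x"], tiny_lexicon)
        b = lsm_pair(["f_conj", "x"], ["f_conj", "x", "x", "x"], tiny_lexicon)
        assert a.mean > b.mean


class TestBootstrap:
    def test_constant_data(self):
        assert bootstrap_ci([3.5] * 10, B=200, seed=1) == (3.5, 3.5, 3.5)

    def test_single_value_collapses(self):
        m, lo, hi = bootstrap_ci([2.0], B=100, seed=0)
        assert m == lo == hi == 2.0

    def test_deterministic_per_seed(self):
        vals = list(np.random.default_rng(3).normal(size=30))
        assert bootstrap_ci(vals, seed=5) == bootstrap_ci(vals, seed=5)
        assert bootstrap_ci(vals, seed=5) != bootstrap_ci(vals, seed=6)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], B=10)
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], B=0)
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], level=1.5)

    def test_matches_scipy_percentile_bootstrap_coverage(self):
        """Same data, same B: agreement with the independent scipy
        implementation of the percentile interval (moderate tolerance; the
        resample streams differ)."""
        from scipy import stats

        rng = np.random.default_rng(4)
        x = rng.exponential(1.0, 150)
        _, lo, hi = bootstrap_ci(x, B=4000, level=0.95, seed=9)
        res = stats.bootstrap(
            (x,), np.mean, n_resamples=4000, method="percentile",
            confidence_level=0.95, random_state=np.random.default_rng(9),
        )
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.02)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.02)

    def test_coverage_of_the_mean(self):
        """~95% empirical coverage for exponential data, n=200."""
        rng = np.random.default_rng(0)
        cover = 0
        for r in range(200):
            x = rng.exponential(1.0, 200)
            _, lo, hi = bootstrap_ci(x, B=500, level=0.95, seed=r)
            cover += lo <= 1.0 <= hi
        assert 0.90 <= cover / 200 <= 0.99


class TestLsmByTopic:
    def make_pairs(self, tiny_lexicon, rng, n=30):
        words = ["f_conj", "f_prep", "f_ppron", "x", "sad"]
        pairs = []
        for i in range(n):
            q = [words[j] for j in rng.integers(0, 5, 20)]
            a = [words[j] for j in rng.integers(0, 5, 20)]
            pairs.append((q, a, i % 2, "AHE" if i % 3 else "ALE"))
        return pairs

    def test_single_pair_degenerate_ci(self, tiny_lexicon):
        pairs = [(["f_conj", "x"], ["f_conj", "y"], 0, "AHE")]
        [s] = lsm_by_topic(pairs, tiny_lexicon, B=100, seed=0)
        assert s.n_pairs == 1
        assert s.ci_low == s.mean == s.ci_high

    def test_order_invariance(self, tiny_lexicon, rng):
        pairs = self.make_pairs(tiny_lexicon, rng)
        a = lsm_by_topic(pairs, tiny_lexicon, B=300, seed=7)
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        b = lsm_by_topic(shuffled, tiny_lexicon, B=300, seed=7)
        assert a == b

    def test_missing_cell_warns(self, tiny_lexicon):
        pairs = [
            (["f_conj"], ["f_conj"], 0, "AHE"),
            (["f_conj"], ["f_conj"], 0, "ALE"),
            (["f_conj"], ["f_conj"], 1, "AHE"),
        ]
        with pytest.warns(UserWarning, match="no ALE pairs"):
            summaries = lsm_by_topic(pairs, tiny_lexicon, B=50, seed=0)
        assert {(s.topic, s.engagement_class) for s in summaries} == {
            (0, "AHE"), (0, "ALE"), (1, "AHE"),
        }

    def test_planted_matching_gap_recovered(self):
        """m_AHE=0.8 vs m_ALE=0.2 -> AHE mean LSM above ALE in every topic."""
        from mhqa import generate_corpus, generate_lexicon, partition_engagement, tokenize, question_text
        from mhqa.synth import SynthConfig

        cfg = SynthConfig(n_questions=300, n_topics=4)
        lex = generate_lexicon(cfg, 21)
        corpus, truth = generate_corpus(cfg, 21, lex)
        part = partition_engagement(corpus)
        topic_of = truth.topic_of()
        qtok = {q.id: tokenize(question_text(q)) for q in corpus.questions()}
        pairs = []
        for a in corpus.answers():
            cls = "AHE" if a.id in part.AHE else ("ALE" if a.id in part.ALE else None)
            if cls:
                pairs.append((qtok[a.parent_id], tokenize(a.body), topic_of[a.parent_id], cls))
        summaries = {(s.topic, s.engagement_class): s for s in
                     lsm_by_topic(pairs, lex, B=500, seed=2)}
        for topic in range(4):
            assert summaries[(topic, "AHE")].mean > summaries[(topic, "ALE")].mean

    def test_equal_matching_centers_difference_on_zero(self):
        """With m_AHE = m_ALE the per-seed AHE-ALE mean difference has no
        systematic sign (sign test over 30 seeds)."""
        from mhqa import generate_corpus, generate_lexicon, partition_engagement, tokenize, question_text
        from mhqa.lsm import lsm_pair
        from mhqa.synth import SynthConfig
        from scipy import stats

        diffs = []
        for seed in range(30):
            cfg = SynthConfig(
                n_questions=40, n_topics=2,
                style_match={"AHE": 0.5, "ALE": 0.5, "midA": 0.5},
            )
            lex = generate_lexicon(cfg, seed)
            corpus, _ = generate_corpus(cfg, seed, lex)
            part = partition_engagement(corpus)
            qtok = {q.id: tokenize(question_text(q)) for q in corpus.questions()}
            vals = {"AHE": [], "ALE": []}
            for a in corpus.answers():
                cls = "AHE" if a.id in part.AHE else ("ALE" if a.id in part.ALE else None)
                if cls:
                    vals[cls].append(lsm_pair(qtok[a.parent_id], tokenize(a.body), lex).mean)
            diffs.append(np.mean(vals["AHE"]) - np.mean(vals["ALE"]))
        n_pos = sum(d > 0 for d in diffs)
        p = stats.binomtest(n_pos, len(diffs), 0.5).pvalue
        assert p > 0.05
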
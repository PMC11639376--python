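# Methods

This note documents the statistical procedures implemented in `mhqa`, the
assumptions behind them, the synthetic data model used to validate them,
and the numerical and design choices a maintainer should know about.

## Data model and filtering

A corpus is a flat list of posts: questions (title, body, platform-reported
reply count) and answers (body, like count, a link to their question).
Threads are single-turn — one question, independent answers — so no
conversational structure beyond the question–answer link is modelled.

Cleaning removes line breaks and whitespace runs, scheme-prefixed URLs and
emoji codepoints; character content is otherwise untouched. Retention rules
then drop questions with fewer than `min_replies` replies (default 1,
together with their answers) and answers whose cleaned body is shorter than
`min_answer_chars` Unicode code points (default 100). Two conventions are
deliberate: the character minimum is counted *after* cleaning (the
unambiguous reading for Chinese text, where code points ≈ characters), and
the full analysis text of a question is `title + " " + body` (titles carry
real signal; discarding them would be a silent loss). Engagement counts are
platform-reported and are never recomputed after filtering: the platform
truth is authoritative, and pruned answers do not reduce a question's
reply count.

Engagement classes contrast extremes: QHE (replies ≥ 6), QLE (replies = 1),
AHE (likes ≥ 10), ALE (likes = 0); all four cut points are configurable.
Posts between the cut points belong to no class and are excluded from
class-based analyses but retained in the corpus — the contrast is
deliberately between clearly-high and clearly-low engagement.

## Category profiles and dominance scores

A category profile pools all tokens of a post set and reports, per lexicon
category, `100 · hits / total tokens`. The denominator counts *every*
token, including words outside the lexicon — the LIWC convention — and
stopwords are never removed at this stage (stopword lists apply only where
a stage explicitly requests them: frequency counting and LDA vocabulary).
Profiles are pooled at class level (all posts concatenated) rather than
averaged per post, because the dominance ratio is defined on class-level
proportions.

The dominance score of category `t` between a high class H and low class L
is `S_t = type%_H(t) / type%_L(t)`. A zero denominator with a positive
numerator is reported as *undefined* (NaN, flagged) rather than smoothed or
imputed; both proportions zero gives `S_t = 1` by convention, flagged
*degenerate*. Identity (`S = 1` against itself) and reciprocity
(`S_HL · S_LH = 1` where defined) are tested invariants.

## Linguistic style matching

Per function-word category `t`, with `p_q` and `p_a` the percentage of the
question's and answer's tokens in `t`:

    LSM_t = 1 − |p_q − p_a| / (p_q + p_a + .0001)

The additive constant is kept exactly as published (it also defines the
both-zero case as a perfect match). The pair score is the arithmetic mean
over the 8 function categories; proportions use the whole post as
denominator, consistent with the profile definition. `LSM_t ∈ (0, 1]`, with
1 iff the proportions coincide.

Pairs (each answer against its own question) are grouped per
(topic, engagement class) and summarized by the mean and a nonparametric
bootstrap percentile CI: B = 1000 resamples of the n pair scores with
replacement, interval at the (1−level)/2 quantiles of the resample means
(level 0.95 default). Resampling is at pair level — the cell's uncertainty
is over which pairs were observed — and the percentile interval (not BCa)
is used as the plain reading of "nonparametric bootstrap". Each cell's
resampling seed is derived from the master seed and the (topic, class) key,
and values are sorted within the cell first, so summaries are invariant to
pair arrival order. scipy's percentile bootstrap serves as an independent
cross-check in the test suite.

## Topic model

LDA with symmetric Dirichlet priors, fitted by collapsed Gibbs sampling
(the inner loop is a numba kernel that owns its RNG, so a (corpus, K,
iters, seed) tuple is bit-reproducible). Point estimates are
`φ_kw = (n_kw + β)/(n_k + Vβ)` and `θ_dk = (n_dk + α)/(n_d + Kα)`.
Defaults: `α = 50/K`, `β = 0.01` (common practice), 40 sweeps for pipeline
runs — the protocol's stated iteration count — and 200 sweeps in recovery
tests, where 40 is rarely enough for clean convergence. Single chains can
occasionally stick in merged-topic modes on corpora of a few hundred
documents; recovery is robust across chain seeds at the tested scale of
D = 800.

LDA consumes raw counts. The upstream protocol feeds TF-IDF vectors
(`tf · log2(D/df)`, L2-normalized) into LDA, which is statistically
non-standard since the model is defined on counts; `fit_lda` therefore
accepts TF-IDF input only behind an explicit `allow_tfidf` flag that rounds
weights to pseudo-counts and logs loudly. Both paths exist so either
reading of the protocol can be reproduced.

K is chosen on a grid by maximizing UMass coherence
(`Σ_{i<j} log((D(w_i,w_j)+1)/D(w_j))` over each topic's top words), with
perplexity `exp(−Σ log p(w|d)/N)` reported alongside — an automated
surrogate for the original visual, judgment-based choice of K
("consistency and perplexity"). Defaults: K = 8 for questions, K = 4 for
answers. Keywords are ranked by λ-relevance,
`λ·log φ_kw + (1−λ)·log(φ_kw/p(w))`, λ = 0.6 (the visualization-community
default; the protocol's λ is unstated). Ties everywhere break to the lower
index for determinism. Documents are hard-assigned to `argmax_k θ_dk`;
documents empty after vocabulary mapping get the sentinel −1.

## Language-model divergence

For classes A and B, each is split 8:1:1 into train/validation/test
(uniform shuffle; valid and test get the floor of their share, remainder to
train). A model trained on A's training split gives

    E_{A,B} = CE(LM_A, B_test) − CE(LM_A, A_test)

in nats. `E(A, A) = 0` by construction and a uniform model gives `E = 0`
for any pair — both are exact test anchors. For unigram models on planted
unigram sources, `E → KL(B‖A) + H(B) − H(A)`; the test suite uses
equal-entropy source pairs so the analytic KL is the reference value.

The reference backend is an interpolated additive-smoothing n-gram model:
`P_k(w|h) = (c(h,w) + δ·P_{k−1}(w|h[1:])) / (c(h) + δ)` recursing to a
uniform base over vocabulary + UNK (order 3, δ = 0.1 default) — fully
deterministic, desk-scale, and strictly positive on any sequence for
δ > 0. An optional recurrent backend mirrors the published training
protocol (LSTM, lr 1e-3, dropout 0.4, SGD, cross-entropy loss, 50 epochs)
and requires the optional `torch` extra; it is not part of the tested
reference path.

Two normalizations are provided. `per_token` (default) divides total log
probability by the number of predicted events; `per_document` averages
document log probabilities as the published formula literally reads, but
conflates document length with style, so the honest default is per-token.
Similarly, the published protocol builds the dictionary from "all words in
the topic" (pooling train and test); the default here is a train-only
dictionary with UNK mapping — no test-vocabulary leakage — with a
`pooled_dictionary` fidelity flag to reproduce the published variant.

## Synthetic corpus generator

The generator is the package's study-condition definition, not a test
convenience. Tokens are symbolic words with lexicon category tags — every
downstream statistic is token-based, so fluent text is unnecessary — and
each structural dimension is planted independently:

* **Lexicon**: vocabulary split into function words (default 160, spread
  evenly over the 8 function categories, one category each) and content
  words tagged with 0–2 of 10 content categories (60% tagged; every
  category guaranteed non-empty).
* **Topics**: planted topic-word distributions are Dirichlet(0.05) draws
  over content words; each question draws θ ~ Dirichlet(0.1) and its
  ground-truth label is the dominant topic. Answers draw content from their
  question's label topic — the pipeline's assumption that answers inherit
  the question's topic is true by construction.
* **Style**: each question owns a style vector over the 8 function
  categories (Dirichlet(5)); an answer's style is
  `(1−m)·base + m·question_style` with per-class matching parameter m
  (defaults m_AHE = 0.8, m_ALE = 0.2, mid 0.5). Mixing on the proportion
  simplex makes the planted LSM effect analytically predictable.
* **Category boosts**: per-class rate multipliers scale designated content
  categories (AHE: negemo 1.5, motion/family 1.3, space 1.2; analogous
  boosts for question classes). The reweighting fixes each boosted word's
  probability at `rate · φ` and renormalizes only over unboosted words, so
  the planted dominance ratio equals the configured rate without
  renormalization bias (up to rare doubly-boosted words).
* **Engagement**: each post draws a latent class, then a count from that
  class's distribution — shifted negative binomials for the high classes
  (over-dispersed, long-tailed), exact constants for QLE (1) and ALE (0),
  uniform draws between the thresholds for the mid bucket. Class shares
  default to {QHE .25, QLE .30, midQ .45} and {AHE .06, ALE .08, midA .86}:
  the extremes are roughly balanced against each other but are minorities
  of total traffic, which reproduces realistic platform marginals (mean
  likes ≈ 5, mean replies ≈ 4, ~3 questions per extreme answer pair).
  Generation validates that ≥ 90% of planted-high answers clear the likes
  threshold and warns otherwise.

Scale defaults mirror a real counseling board at desk size: 3.5 answers
per question, ~140-token question bodies, ~12-token titles, ~335-token
answers (≈ 240/570 characters at typical Chinese token lengths),
`function_word_rate` 0.35, 8 topics, vocabulary 2000. Bodies are tokens
joined by single spaces, so the whitespace tokenizer inverts generation
exactly; a mean-token-length adapter view makes the 100-character filter
exercisable.

What the generator does **not** emulate: syntax and discourse (tokens are
exchangeable given their distributions), answer-length/engagement
correlations, temporal drift, and any dependence of engagement on content
beyond the planted class structure. Passing recovery tests therefore
demonstrate that the estimators recover known effects of realistic
magnitude from realistic sample sizes — not that such effects exist in any
real platform's data.

## Reproducibility and problem sizes

One master seed drives everything: pipeline stages derive seeds from
(master, stage index); the generator derives per-post streams from
(seed, post counter); LSM cells derive resampling seeds from the cell key.
The full pipeline is byte-reproducible for a (config, seed) pair with the
n-gram backend.

Validation problem sizes were chosen as the smallest scales at which the
estimators' sampling error is well below the planted effects: topic
recovery on 800 length-60 documents (K = 4, V = 400, 200 sweeps, mean
matched total-variation ≈ 0.04); style-matching recovery over 20 seeds
with ~100 pairs per topic-class cell (~3800 questions per seed); bootstrap
calibration with 500 replications of n = 200; language-model divergence on
50k-token corpora against an analytic 0.5-nat KL.

## Known limitations

* The Gibbs sampler is single-chain; no convergence diagnostics beyond the
  monotone-perplexity property test. Multiple restarts are the caller's
  responsibility on small corpora.
* `select_k` automates a judgment call; UMass coherence is one proxy for
  topic "consistency" and can disagree with human inspection.
* The n-gram backend measures divergence in distributional/stylistic
  vocabulary use; it is blind to long-range structure that a recurrent
  model might capture.
* Dominance scores are descriptive ratios without uncertainty intervals;
  treat small-sample scores near 1 with caution (the undefined/degenerate
  flags mark the hard cases only).
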
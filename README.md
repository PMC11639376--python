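# mhqa — psycholinguistic engagement analysis of counseling Q&A corpora

`mhqa` is a Python library for analysing how linguistic behaviour differs
between high- and low-engagement posts on online mental-health Q&A
platforms, where help-seekers post questions (engagement = reply count) and
credentialed counselors post answers (engagement = like count). It is aimed
at computational-social-science and psycholinguistics researchers who work
with LIWC-style category lexicons and platform text dumps.

The analysis contrasts the engagement extremes — questions with replies ≥ 6
(QHE) vs exactly 1 (QLE), answers with likes ≥ 10 (AHE) vs 0 (ALE) — along
four axes:

1. **Category dominance.** With `type%_C(t)` the proportion of tokens of
   class `C` falling in lexicon category `t`, the dominance score
   `S_t = type%_high / type%_low` quantifies over-use of `t` by the
   high-engagement class (`S_t = 1` is parity).
2. **Linguistic style matching (LSM).** For a question `q` and answer `a`,
   per function-word category `t`:
   `LSM_t = 1 − |type%_q − type%_a| / (type%_q + type%_a + .0001)`,
   averaged over 8 closed-class categories (auxiliary verbs, adverbs,
   personal/impersonal pronouns, prepositions, negations, conjunctions,
   quantifiers — no article category, as Chinese has none). Pair scores are
   aggregated per (topic, class) with nonparametric bootstrap percentile
   CIs.
3. **Topic structure.** LDA via collapsed Gibbs sampling
   (`φ_kw ∝ n_kw + β`, `θ_dk ∝ n_dk + α`), with perplexity and UMass
   coherence for choosing K, and λ-relevance-ranked topic keywords.
4. **Language-model divergence.** With a model `LM_A` trained on class A's
   training split, `E_{A,B} = CE(LM_A, B_test) − CE(LM_A, A_test)`;
   `E > 0` means B's language is harder for A's model than A's own held-out
   text. The reference backend is a deterministic interpolated
   additive-smoothing n-gram model.

Because real platform dumps of this kind are typically private, the package
ships a first-class synthetic-corpus generator (`mhqa.synth`) that plants
topics, engagement classes, category-usage boosts and a style-matching
parameter, with full ground truth for parameter-recovery validation.

## Worked example

```python
from mhqa import (SynthConfig, generate_corpus, generate_lexicon,
                  partition_engagement, lsm_by_topic, question_text, tokenize)

cfg = SynthConfig(n_questions=1200, n_topics=4)
lexicon = generate_lexicon(cfg, seed=3)
corpus, truth = generate_corpus(cfg, seed=3, lexicon=lexicon)
part = partition_engagement(corpus)

topic_of = truth.topic_of()
qtok = {q.id: tokenize(question_text(q)) for q in corpus.questions()}
pairs = [(qtok[a.parent_id], tokenize(a.body), topic_of[a.parent_id],
          "AHE" if a.id in part.AHE else "ALE")
         for a in corpus.answers() if a.id in part.AHE or a.id in part.ALE]
for s in lsm_by_topic(pairs, lexicon, B=1000, seed=0):
    print(s.topic, s.engagement_class, s.n_pairs,
          round(s.mean, 4), round(s.ci_low, 4), round(s.ci_high, 4))
```

prints (`topic class n mean ci_low ci_high`):

```
0 AHE 57 0.7705 0.747  0.791
0 ALE 64 0.6961 0.6781 0.7161
1 AHE 55 0.7582 0.7348 0.7797
1 ALE 83 0.6852 0.6638 0.7064
2 AHE 58 0.7589 0.734  0.7816
2 ALE 73 0.7056 0.6838 0.7288
3 AHE 75 0.7674 0.7427 0.7904
3 ALE 88 0.7115 0.6941 0.728
```

The generator planted matching parameters m=0.8 for AHE and m=0.2 for ALE:
in every topic the AHE mean LSM is higher and the 95% bootstrap CIs of the
two classes are disjoint — high-engagement answers track the question's
function-word style, low-engagement answers do not.

The `examples/` directory has one short narrative script per capability
(corpus generation, dominance, topics, LSM, entropy divergence, full
pipeline). The full pipeline is also exposed as a thin CLI:

```bash
mhqa synth --seed 4 --out scratch/demo          # corpus + lexicon + truth
mhqa run --config examples/pipeline.yaml        # all stages -> report.txt
```

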
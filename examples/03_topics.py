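"""LDA topic structure: fitting, model selection, keywords, assignment.

Collapsed Gibbs LDA on a planted-topic corpus; K is chosen on a grid by
UMass coherence (with perplexity reported), and topics are summarized by
their lambda-relevance-ranked keywords.
"""

from mhqa import (
    SynthConfig,
    assign_topics,
    build_vocab,
    fit_lda,
    generate_corpus,
    perplexity,
    select_k,
    to_bow,
    tokenize,
    top_keywords,
)
from mhqa.synth import LengthSpec

cfg = SynthConfig(
    n_questions=300, n_topics=4, vocab_size=400, n_function_words=16,
    function_word_rate=0.0, question_len=LengthSpec(60, float("inf")),
    title_len=LengthSpec(0), answers_per_question=LengthSpec(0),
)
corpus, truth = generate_corpus(cfg, seed=2)
docs = [tokenize(q.body) for q in corpus.questions()]
vocab = build_vocab(docs, min_count=2)
bow = to_bow(docs, vocab)

report = select_k(bow, [2, 4, 8], iters=60, alpha=0.1, seed=0)
print(report.to_frame().to_string(index=False, float_format="{:.3f}".format))
print(f"chosen K = {report.chosen_k} (planted K = {cfg.n_topics})")

model = fit_lda(bow, report.chosen_k, iters=200, alpha=0.1, beta=0.01, seed=0)
print(f"training perplexity: {perplexity(model, bow):.2f}")
for k in range(model.K):
    words = [vocab.id2word[i] for i in top_keywords(model, k, n=8, lam=0.6, bow=bow)]
    print(f"topic {k}: {' '.join(words)}")
labels = assign_topics(model, bow)
print(f"documents per topic: {[int((labels == k).sum()) for k in range(model.K)]}")
# Coherence should peak at the planted K; keyword lists are disjoint word
# sets because planted topics are near-disjoint sparse distributions.
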
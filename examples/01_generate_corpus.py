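"""Generate a synthetic counseling Q&A corpus with planted ground truth.

The generator emulates a mental-health Q&A board: questions with reply
counts, counselor answers with like counts, eight planted question topics,
and engagement-dependent vocabulary and style structure.
"""

from mhqa import SynthConfig, generate_corpus, generate_lexicon

cfg = SynthConfig(n_questions=200)
lexicon = generate_lexicon(cfg, seed=0)
corpus, truth = generate_corpus(cfg, seed=0, lexicon=lexicon)

print(corpus)
q = corpus.questions()[0]
print(f"first question ({q.id}): reply_count={q.reply_count}, "
      f"{len(q.body.split())} body tokens")
print(f"its answers: {[a.id for a in corpus.answers_of(q.id)]}")
print(f"planted topic of {q.id}: {truth.topic_of()[q.id]}")
print(f"lexicon: {len(lexicon.categories)} categories, "
      f"{len(lexicon.function_categories)} function-word categories")
# Reply/like counts are drawn per planted engagement class, so the corpus
# contains high-, low- and mid-engagement posts in platform-like shares.
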
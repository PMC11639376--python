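"""Category dominance between high- and low-engagement answers.

The dominance score of a vocabulary category t is the ratio of t's token
proportion in the high-engagement class to the low-engagement class
(S_t = type%_AHE / type%_ALE).  S_t > 1 means high-engagement answers
over-use the category; the generator plants a 1.5x negative-emotion boost.
"""

from mhqa import (
    SynthConfig,
    category_profile,
    dominance_scores,
    generate_corpus,
    generate_lexicon,
    partition_engagement,
    tokenize,
)

cfg = SynthConfig(n_questions=800)
lexicon = generate_lexicon(cfg, seed=1)
corpus, _ = generate_corpus(cfg, seed=1, lexicon=lexicon)
part = partition_engagement(corpus)

ahe = [tokenize(p.body) for p in corpus.answers() if p.id in part.AHE]
ale = [tokenize(p.body) for p in corpus.answers() if p.id in part.ALE]
table = dominance_scores(
    category_profile(ahe, lexicon), category_profile(ale, lexicon), "AHE", "ALE"
)
print(table.to_frame().to_string(index=False, float_format="{:.3f}".format))
# Planted boosts (negemo 1.5, motion/family 1.3, space 1.2) surface as
# scores near those rates; unboosted categories sit near 1.0 (parity).
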
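"""Language-model entropy differences between engagement classes.

A smoothed trigram model trained on class A's training split is evaluated
on held-out text of both classes; E = CE(B_test) - CE(A_test) > 0 means B's
language diverges from A's.  Both directions are computed (LMAHE, LMALE).
"""

from mhqa import (
    LmConfig,
    SynthConfig,
    generate_corpus,
    paired_divergence,
    partition_engagement,
    tokenize,
)

cfg = SynthConfig(n_questions=1200)
corpus, _ = generate_corpus(cfg, seed=4)
part = partition_engagement(corpus)
ahe = [tokenize(p.body) for p in corpus.answers() if p.id in part.AHE]
ale = [tokenize(p.body) for p in corpus.answers() if p.id in part.ALE]
print(f"{len(ahe)} AHE and {len(ale)} ALE answers")

res_hi, res_lo = paired_divergence(
    ahe, ale, LmConfig(order=3, smoothing=0.1), seed=0, labels=("LMAHE", "LMALE")
)
for r in (res_hi, res_lo):
    print(f"{r.model_class}: H_own={r.h_own:.3f} H_other={r.h_other:.3f} "
          f"E={r.entropy_difference:+.4f} nats/token")
# Both E values are positive: each class's model finds the other class's
# held-out text harder than its own, i.e. the planted vocabulary and style
# differences are visible to a language model.
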
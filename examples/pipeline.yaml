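# Full-pipeline configuration on a synthetic corpus.
# Every field mirrors a PipelineConfig attribute; omitted fields keep their
# defaults (8 question topics / 4 answer topics, 40 Gibbs sweeps, top-30
# keywords at lambda=0.6, B=1000 bootstrap at level 0.95, trigram LM).
seed: 7
out_dir: scratch/pipeline_yaml_demo
synth:
  n_questions: 400
  n_topics: 4
lda:
  k_questions: 4
  k_answers: 2
  iters: 40
  n_keywords: 10
lsm:
  B: 1000
  level: 0.95
lm:
  per_topic: false
  min_docs: 5
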
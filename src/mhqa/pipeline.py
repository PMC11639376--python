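"""End-to-end analysis pipeline.

Stages: load/generate corpus -> clean & filter -> engagement partition ->
question/answer topic models -> category dominance (QHE/QLE and AHE/ALE) ->
per-topic LSM with bootstrap CIs -> per-topic language-model entropy
differences for the four class models (LMQHE, LMQLE, LMAHE, LMALE).

A single master seed drives every stage; per-stage seeds are derived from a
fixed stage counter (the order of ``STAGES``), so a (config, seed) pair
yields a byte-identical report.  Every intermediate table is persisted under
the output directory so each reported number can be re-derived.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lsm as lsm_mod
from .corpus import (
    Corpus,
    EngagementPartition,
    FilterConfig,
    clean_text,
    filter_corpus,
    partition_engagement,
    question_text,
    read_corpus,
    tokenize,
    write_corpus,
)
from .lexicon import CategoryLexicon, category_profile, dominance_scores, read_lexicon
from .lm import LmConfig, paired_divergence
from .synth import SynthConfig, generate_corpus, generate_lexicon
from .topics import assign_topics, build_vocab, fit_lda, to_bow, top_keywords

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "render_report", "PipelineError"]

# Stage order defines the per-stage seed derivation (seed, stage index).
STAGES = (
    "generate",
    "clean_filter",
    "partition",
    "topics_questions",
    "topics_answers",
    "dominance",
    "lsm",
    "lm_divergence",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([master, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class LdaSettings:
    k_questions: int = 8
    k_answers: int = 4
    iters: int = 40
    alpha: float | None = None
    beta: float = 0.01
    lam: float = 0.6
    n_keywords: int = 30
    min_count: int = 2


@dataclass
class LsmSettings:
    B: int = 1000
    level: float = 0.95


@dataclass
class LmSettings:
    enabled: bool = True
    backend: str = "ngram"
    order: int = 3
    smoothing: float = 0.1
    normalization: str = "per_token"
    per_topic: bool = True
    min_docs: int = 10  # per class per topic; smaller cells are skipped


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "mhqa_out"
    corpus_path: str | None = None  # read an existing corpus ...
    corpus_format: str = "jsonl"
    synth: SynthConfig | None = None  # ... or generate one
    lexicon_path: str | None = None  # defaults to the synthetic lexicon
    stopwords_path: str | None = None
    tokenizer: str = "whitespace"
    filter: FilterConfig = field(default_factory=FilterConfig)
    engagement: EngagementPartition = field(default_factory=EngagementPartition)
    lda: LdaSettings = field(default_factory=LdaSettings)
    lsm: LsmSettings = field(default_factory=LsmSettings)
    lm: LmSettings = field(default_factory=LmSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synth" in kwargs and kwargs["synth"] is not None:
            kwargs["synth"] = _build_dataclass(SynthConfig, kwargs["synth"])
        for key, klass in (
            ("filter", FilterConfig),
            ("engagement", EngagementPartition),
            ("lda", LdaSettings),
            ("lsm", LsmSettings),
            ("lm", LmSettings),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


def _build_dataclass(klass, raw: dict):
    from .synth import LengthSpec

    kwargs = dict(raw)
    for name in ("answers_per_question", "title_len", "question_len", "answer_len"):
        if name in kwargs and isinstance(kwargs[name], dict):
            kwargs[name] = LengthSpec(**kwargs[name])
    return klass(**kwargs)


@dataclass
class AnalysisReport:
    """All tables of one pipeline run, plus the config echo."""

    corpus_summary: pd.DataFrame
    class_sizes: pd.DataFrame
    keywords_questions: pd.DataFrame
    keywords_answers: pd.DataFrame
    dominance_questions: pd.DataFrame
    dominance_answers: pd.DataFrame
    lsm_summary: pd.DataFrame
    entropy: pd.DataFrame | None
    config_echo: str
    seed: int


def _summary_table(corpus: Corpus) -> pd.DataFrame:
    qs, ans = corpus.questions(), corpus.answers()
    def _stats(values):
        if not values:
            return 0.0, 0.0
        arr = np.array(values, dtype=float)
        return float(arr.mean()), float(np.median(arr))
    qt_mean, qt_med = _stats([len(q.title) for q in qs])
    qb_mean, qb_med = _stats([len(q.body) for q in qs])
    ab_mean, ab_med = _stats([len(a.body) for a in ans])
    likes = [a.like_count for a in ans]
    replies = [q.reply_count for q in qs]
    rows = [
        ("number of questions", len(qs)),
        ("number of answers", len(ans)),
        ("mean/median question title chars", f"{qt_mean:.6g}/{qt_med:.6g}"),
        ("mean/median question body chars", f"{qb_mean:.6g}/{qb_med:.6g}"),
        ("mean/median answer body chars", f"{ab_mean:.6g}/{ab_med:.6g}"),
        ("mean/max likes per answer",
         f"{(np.mean(likes) if likes else 0):.6g}/{(max(likes) if likes else 0)}"),
        ("mean/max replies per question",
         f"{(np.mean(replies) if replies else 0):.6g}/{(max(replies) if replies else 0)}"),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        lexicon: CategoryLexicon | None = None
        if config.corpus_path is not None:
            corpus = read_corpus(config.corpus_path, config.corpus_format)
        elif config.synth is not None:
            seed = stage_seed(config.seed, "generate")
            lexicon = generate_lexicon(config.synth, seed)
            corpus, truth = generate_corpus(config.synth, seed, lexicon)
            truth.write(out / "ground_truth")
        else:
            raise ValueError("config needs corpus_path or synth")
        if config.lexicon_path is not None:
            lexicon = read_lexicon(config.lexicon_path)
        if lexicon is None:
            raise ValueError("no lexicon: set lexicon_path or synth")
        _log(stage, n_posts=len(corpus))

        stage = "clean_filter"
        cleaned = Corpus(
            [
                dataclasses.replace(
                    p, title=clean_text(p.title), body=clean_text(p.body), tokens=None
                )
                for p in corpus
            ]
        )
        filtered = filter_corpus(cleaned, config.filter)
        write_corpus(filtered, out / "corpus_filtered.jsonl")
        _log(stage, kept=len(filtered), dropped=len(corpus) - len(filtered))

        stage = "partition"
        part = partition_engagement(filtered, config.engagement)
        (out / "partition.json").write_text(
            json.dumps(
                {c: sorted(getattr(part, c)) for c in ("QHE", "QLE", "AHE", "ALE")},
                indent=1,
            )
        )
        class_sizes = pd.DataFrame(
            {
                "class": ["QHE", "QLE", "AHE", "ALE"],
                "n": [len(part.QHE), len(part.QLE), len(part.AHE), len(part.ALE)],
            }
        )
        n_q, n_a = len(filtered.questions()), len(filtered.answers())
        class_sizes["share"] = [
            (n / n_q if cls.startswith("Q") else n / n_a) if (n_q and n_a) else 0.0
            for cls, n in zip(class_sizes["class"], class_sizes["n"])
        ]
        _log(stage, **dict(zip(class_sizes["class"], class_sizes["n"])))

        stopwords: frozenset[str] = frozenset()
        if config.stopwords_path:
            stopwords = frozenset(
                Path(config.stopwords_path).read_text(encoding="utf-8").split()
            )

        # tokenize once, cache on posts
        for p in filtered:
            text = question_text(p) if p.is_question else p.body
            p.tokens = tokenize(text, config.tokenizer)

        stage = "topics_questions"
        questions = filtered.questions()
        q_tokens = [q.tokens for q in questions]
        q_vocab = build_vocab(q_tokens, config.lda.min_count, stopwords)
        q_bow = to_bow(q_tokens, q_vocab)
        q_model = fit_lda(
            q_bow,
            config.lda.k_questions,
            iters=config.lda.iters,
            alpha=config.lda.alpha,
            beta=config.lda.beta,
            seed=stage_seed(config.seed, "topics_questions"),
        )
        q_labels = assign_topics(q_model, q_bow)
        topic_of_q = {q.id: int(t) for q, t in zip(questions, q_labels)}
        kw_q = _keyword_table(q_model, q_bow, q_vocab, config.lda)
        kw_q.to_csv(out / "keywords_questions.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"question_id": [q.id for q in questions], "topic": q_labels}
        ).to_csv(out / "question_topics.tsv", sep="\t", index=False)
        _log(stage, K=config.lda.k_questions, vocab=len(q_vocab))

        stage = "topics_answers"
        answers = filtered.answers()
        kw_a = pd.DataFrame(columns=["topic", "rank", "word"])
        if answers:
            a_tokens = [a.tokens for a in answers]
            a_vocab = build_vocab(a_tokens, config.lda.min_count, stopwords)
            a_bow = to_bow(a_tokens, a_vocab)
            a_model = fit_lda(
                a_bow,
                config.lda.k_answers,
                iters=config.lda.iters,
                alpha=config.lda.alpha,
                beta=config.lda.beta,
                seed=stage_seed(config.seed, "topics_answers"),
            )
            kw_a = _keyword_table(a_model, a_bow, a_vocab, config.lda)
        kw_a.to_csv(out / "keywords_answers.tsv", sep="\t", index=False)
        _log(stage, K=config.lda.k_answers)

        stage = "dominance"
        def _class_docs(ids):
            return [filtered.by_id[i].tokens for i in sorted(ids)]
        dom_q = dom_a = pd.DataFrame()
        if part.QHE and part.QLE:
            dom_q = dominance_scores(
                category_profile(_class_docs(part.QHE), lexicon),
                category_profile(_class_docs(part.QLE), lexicon),
                "QHE", "QLE",
            ).to_frame()
        if part.AHE and part.ALE:
            dom_a = dominance_scores(
                category_profile(_class_docs(part.AHE), lexicon),
                category_profile(_class_docs(part.ALE), lexicon),
                "AHE", "ALE",
            ).to_frame()
        dom_q.to_csv(out / "dominance_questions.tsv", sep="\t", index=False)
        dom_a.to_csv(out / "dominance_answers.tsv", sep="\t", index=False)
        _log(stage, q_cats=len(dom_q), a_cats=len(dom_a))

        stage = "lsm"
        pairs = []
        for a in answers:
            cls = "AHE" if a.id in part.AHE else ("ALE" if a.id in part.ALE else None)
            if cls is None:
                continue
            topic = topic_of_q.get(a.parent_id, -1)
            if topic < 0:
                continue
            q = filtered.by_id[a.parent_id]
            pairs.append((q.tokens, a.tokens, topic, cls))
        summaries = lsm_mod.lsm_by_topic(
            pairs,
            lexicon,
            B=config.lsm.B,
            level=config.lsm.level,
            seed=stage_seed(config.seed, "lsm"),
        )
        lsm_table = lsm_mod.summaries_to_frame(summaries)
        lsm_table.to_csv(out / "lsm_summary.tsv", sep="\t", index=False)
        _log(stage, n_pairs=len(pairs), n_cells=len(summaries))

        stage = "lm_divergence"
        entropy_table: pd.DataFrame | None = None
        if config.lm.enabled:
            lm_cfg = LmConfig(
                backend=config.lm.backend,
                order=config.lm.order,
                smoothing=config.lm.smoothing,
            )
            lm_seed = stage_seed(config.seed, "lm_divergence")
            rows = []
            jobs = []
            # question classes grouped by the question's topic; answers inherit
            for topic in sorted({t for t in topic_of_q.values() if t >= 0}):
                docs_cls = {
                    "QHE": [
                        filtered.by_id[i].tokens
                        for i in sorted(part.QHE)
                        if topic_of_q.get(i) == topic
                    ],
                    "QLE": [
                        filtered.by_id[i].tokens
                        for i in sorted(part.QLE)
                        if topic_of_q.get(i) == topic
                    ],
                    "AHE": [
                        a.tokens for a in answers
                        if a.id in part.AHE and topic_of_q.get(a.parent_id) == topic
                    ],
                    "ALE": [
                        a.tokens for a in answers
                        if a.id in part.ALE and topic_of_q.get(a.parent_id) == topic
                    ],
                }
                jobs.append((topic, docs_cls))
            if not config.lm.per_topic:
                merged = {c: [] for c in ("QHE", "QLE", "AHE", "ALE")}
                for _, docs_cls in jobs:
                    for c in merged:
                        merged[c].extend(docs_cls[c])
                jobs = [("all", merged)]
            for topic, docs_cls in jobs:
                for hi, lo in (("QHE", "QLE"), ("AHE", "ALE")):
                    if (
                        len(docs_cls[hi]) < config.lm.min_docs
                        or len(docs_cls[lo]) < config.lm.min_docs
                    ):
                        logger.info(
                            "lm_divergence: skipping topic %s %s/%s (too few docs)",
                            topic, hi, lo,
                        )
                        continue
                    res_hi, res_lo = paired_divergence(
                        docs_cls[hi],
                        docs_cls[lo],
                        lm_cfg,
                        seed=lm_seed,
                        labels=(f"LM{hi}", f"LM{lo}"),
                        normalization=config.lm.normalization,
                        topic=topic,
                    )
                    for r in (res_hi, res_lo):
                        rows.append(
                            {
                                "topic": r.topic,
                                "model_class": r.model_class,
                                "h_own": r.h_own,
                                "h_other": r.h_other,
                                "entropy_difference": r.entropy_difference,
                                "normalization": r.normalization,
                                "backend": config.lm.backend,
                            }
                        )
            entropy_table = pd.DataFrame(rows)
            entropy_table.to_csv(out / "entropy_differences.tsv", sep="\t", index=False)
            _log(stage, n_rows=len(entropy_table))

        config_echo = yaml.safe_dump(_config_to_dict(config), sort_keys=True)
        report = AnalysisReport(
            corpus_summary=_summary_table(filtered),
            class_sizes=class_sizes,
            keywords_questions=kw_q,
            keywords_answers=kw_a,
            dominance_questions=dom_q,
            dominance_answers=dom_a,
            lsm_summary=lsm_table,
            entropy=entropy_table,
            config_echo=config_echo,
            seed=config.seed,
        )
        render_report(report, out / "report.txt", "text")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _keyword_table(model, bow, vocab, lda_cfg: LdaSettings) -> pd.DataFrame:
    rows = []
    for k in range(model.K):
        ids = top_keywords(model, k, n=lda_cfg.n_keywords, lam=lda_cfg.lam, bow=bow)
        for rank, i in enumerate(ids, start=1):
            rows.append({"topic": k, "rank": rank, "word": vocab.id2word[i]})
    return pd.DataFrame(rows)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, list):
        return [_sanitize(v) for v in obj]
    return obj


def _config_to_dict(config: PipelineConfig) -> dict:
    return _sanitize(dataclasses.asdict(config))


def _log(stage: str, **kv) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


_FLOAT_FMT = "{:.6g}".format


def _fmt_table(df: pd.DataFrame) -> str:
    if df is None or df.empty:
        return "(empty)\n"
    return df.to_string(index=False, float_format=_FLOAT_FMT) + "\n"


def render_report(report: AnalysisReport, path: str | Path, format: str = "text") -> None:
    """Render the report; numbers at 6 significant digits; deterministic."""
    path = Path(path)
    sections = [
        ("Corpus summary", report.corpus_summary),
        ("Engagement class sizes", report.class_sizes),
        ("Question topic keywords", report.keywords_questions),
        ("Answer topic keywords", report.keywords_answers),
        ("Dominance scores: QHE vs QLE", report.dominance_questions),
        ("Dominance scores: AHE vs ALE", report.dominance_answers),
        ("LSM by topic and class", report.lsm_summary),
    ]
    if report.entropy is not None:
        sections.append(("Entropy differences", report.entropy))
    if format == "text":
        parts = [f"mhqa analysis report (seed {report.seed})\n"]
        for title, df in sections:
            parts.append(f"\n== {title} ==\n{_fmt_table(df)}")
        parts.append("\n== Configuration ==\n" + report.config_echo)
        path.write_text("".join(parts), encoding="utf-8")
        return
    if format == "html":
        body = [f"<h1>mhqa analysis report (seed {report.seed})</h1>"]
        for title, df in sections:
            body.append(f"<h2>{title}</h2>")
            if df is None or df.empty:
                body.append("<p>(empty)</p>")
            else:
                body.append(df.to_html(index=False, float_format=_FLOAT_FMT))
        body.append("<h2>Configuration</h2><pre>" + report.config_echo + "</pre>")
        html = (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>mhqa report</title></head><body>"
            + "\n".join(body)
            + "</body></html>\n"
        )
        path.write_text(html, encoding="utf-8")
        return
    raise ValueError(f"unknown report format {format!r}")
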
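"""Q&A corpus data model: posts, I/O, cleaning, filtering, engagement partition.

A corpus holds single-turn question/answer threads from an online counseling
platform: help-seekers post questions (with a platform-reported reply count),
credentialed counselors post answers (with a like count).  Engagement analyses
downstream compare the linguistic behaviour of the high- and low-engagement
extremes of both post types.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

__all__ = [
    "Post",
    "Corpus",
    "FilterConfig",
    "EngagementPartition",
    "read_corpus",
    "write_corpus",
    "clean_text",
    "filter_corpus",
    "tokenize",
    "register_segmenter",
    "partition_engagement",
    "question_text",
    "CorpusFormatError",
]


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or inconsistent post collections."""


@dataclass
class Post:
    """One question or answer record.

    ``reply_count`` is meaningful for questions, ``like_count`` for answers;
    both are platform-reported engagement counts and are never recomputed from
    the corpus itself.  ``tokens`` is a cache populated by analysis stages and
    is excluded from serialization and equality.
    """

    id: str
    role: str  # "question" | "answer"
    parent_id: str = ""
    title: str = ""
    body: str = ""
    reply_count: int = 0
    like_count: int = 0
    tokens: list[str] | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.role not in ("question", "answer"):
            raise ValueError(f"post {self.id!r}: unknown role {self.role!r}")
        if self.reply_count < 0 or self.like_count < 0:
            raise ValueError(f"post {self.id!r}: negative engagement count")
        if self.role == "answer" and not self.parent_id:
            raise ValueError(f"answer {self.id!r} has no parent_id")

    @property
    def is_question(self) -> bool:
        return self.role == "question"


def question_text(post: Post) -> str:
    """Full analysis text of a question: title and body joined by one space."""
    if post.title and post.body:
        return post.title + " " + post.body
    return post.title or post.body


class Corpus:
    """Ordered collection of posts with a question-id -> answers index."""

    def __init__(self, posts: Iterable[Post] = ()):
        self.posts: list[Post] = list(posts)
        self.by_id: dict[str, Post] = {}
        self.index: dict[str, list[Post]] = {}
        self._build_index()

    def _build_index(self) -> None:
        self.by_id.clear()
        self.index.clear()
        for post in self.posts:
            if post.id in self.by_id:
                raise CorpusFormatError(f"duplicate post id {post.id!r}")
            self.by_id[post.id] = post
            if post.is_question:
                self.index.setdefault(post.id, [])
        dangling = []
        for post in self.posts:
            if not post.is_question:
                if post.parent_id not in self.index:
                    dangling.append(post.id)
                else:
                    self.index[post.parent_id].append(post)
        if dangling:
            raise CorpusFormatError(
                "answers reference missing questions: " + ", ".join(sorted(dangling))
            )

    def questions(self) -> list[Post]:
        return [p for p in self.posts if p.is_question]

    def answers(self) -> list[Post]:
        return [p for p in self.posts if not p.is_question]

    def answers_of(self, question_id: str) -> list[Post]:
        return self.index.get(question_id, [])

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.posts == other.posts

    def __repr__(self) -> str:
        return f"Corpus({len(self.questions())} questions, {len(self.answers())} answers)"


@dataclass
class FilterConfig:
    """Retention rules: questions need >= ``min_replies`` replies; answers need
    >= ``min_answer_chars`` characters of (cleaned) body text."""

    min_replies: int = 1
    min_answer_chars: int = 100

    def __post_init__(self) -> None:
        if self.min_replies < 0 or self.min_answer_chars < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class EngagementPartition:
    """Engagement class thresholds and the resulting id sets.

    Questions with replies >= ``qhe_min_replies`` are high engagement (QHE),
    replies == ``qle_replies`` low engagement (QLE); answers with likes >=
    ``ahe_min_likes`` are AHE, likes == ``ale_likes`` ALE.  Posts between the
    two cut points belong to no class: the analysis contrasts extremes.
    """

    qhe_min_replies: int = 6
    qle_replies: int = 1
    ahe_min_likes: int = 10
    ale_likes: int = 0
    QHE: frozenset[str] = frozenset()
    QLE: frozenset[str] = frozenset()
    AHE: frozenset[str] = frozenset()
    ALE: frozenset[str] = frozenset()

    def class_of(self, post: Post) -> str | None:
        """Class label for a post, or None if it falls between thresholds."""
        if post.is_question:
            if post.reply_count >= self.qhe_min_replies:
                return "QHE"
            if post.reply_count == self.qle_replies:
                return "QLE"
        else:
            if post.like_count >= self.ahe_min_likes:
                return "AHE"
            if post.like_count == self.ale_likes:
                return "ALE"
        return None


# --- text cleaning ---------------------------------------------------------

_URL_RE = re.compile(r"[A-Za-z][A-Za-z0-9+.-]*://\S+")
# Emoji / emoticon codepoint blocks (pictographs, transport, supplemental
# symbols, dingbats, misc symbols, flags, variation selectors, ZWJ).
_EMOJI_RE = re.compile(
    "["
    "\U0001F000-\U0001FAFF"
    "\U00002600-\U000027BF"
    "\U0001F1E6-\U0001F1FF"
    "\U00002B00-\U00002BFF"
    "︎️‍"
    "]+"
)
_WS_RE = re.compile(r"\s+")


def clean_text(raw: str, extra_patterns: Sequence[str] = ()) -> str:
    """Strip line breaks, redundant whitespace, URLs and emoticons.

    Character content is otherwise preserved in order.  ``extra_patterns`` are
    additional regexes removed before whitespace normalisation (platform-
    specific advertising boilerplate, custom emoticon codes).  The result may
    be empty; retention is the caller's decision.
    """
    text = _URL_RE.sub(" ", raw)
    text = _EMOJI_RE.sub(" ", text)
    for pat in extra_patterns:
        text = re.sub(pat, " ", text)
    return _WS_RE.sub(" ", text).strip()


def filter_corpus(corpus: Corpus, cfg: FilterConfig | None = None) -> Corpus:
    """Apply the retention rules; returns a new corpus, input order preserved.

    Questions failing the reply rule are dropped together with their answers.
    Character counting is Unicode code points of the body. Engagement counts
    are platform-reported and are NOT recomputed after filtering.
    """
    cfg = cfg or FilterConfig()
    keep_q = {
        p.id for p in corpus.posts if p.is_question and p.reply_count >= cfg.min_replies
    }
    kept = []
    for post in corpus.posts:
        if post.is_question:
            if post.id in keep_q:
                kept.append(post)
        else:
            if post.parent_id in keep_q and len(post.body) >= cfg.min_answer_chars:
                kept.append(post)
    return Corpus(kept)


def partition_engagement(
    corpus: Corpus, thresholds: EngagementPartition | None = None
) -> EngagementPartition:
    """Partition posts into the four engagement classes by threshold."""
    t = thresholds or EngagementPartition()
    buckets: dict[str, set[str]] = {"QHE": set(), "QLE": set(), "AHE": set(), "ALE": set()}
    for post in corpus.posts:
        cls = t.class_of(post)
        if cls is not None:
            buckets[cls].add(post.id)
    return replace(
        t,
        QHE=frozenset(buckets["QHE"]),
        QLE=frozenset(buckets["QLE"]),
        AHE=frozenset(buckets["AHE"]),
        ALE=frozenset(buckets["ALE"]),
    )


# --- tokenization ----------------------------------------------------------

_SEGMENTERS: dict[str, Callable[[str], list[str]]] = {}


def register_segmenter(name: str, fn: Callable[[str], list[str]]) -> None:
    """Register a word-segmentation callable for ``tokenize(..., 'segmenter')``."""
    _SEGMENTERS[name] = fn


def tokenize(text: str, backend: str = "whitespace", segmenter: str | None = None) -> list[str]:
    """Deterministic tokenization.

    ``whitespace`` splits on whitespace runs; ``char`` yields one token per
    non-space character (a reasonable fallback for unsegmented Chinese);
    ``segmenter`` delegates to a registered adapter or, failing that, to the
    jieba segmenter if importable.
    """
    if backend == "whitespace":
        return text.split()
    if backend == "char":
        return [c for c in text if not c.isspace()]
    if backend == "segmenter":
        if segmenter is not None and segmenter in _SEGMENTERS:
            return list(_SEGMENTERS[segmenter](text))
        if _SEGMENTERS and segmenter is None:
            name = sorted(_SEGMENTERS)[0]
            return list(_SEGMENTERS[name](text))
        try:
            import jieba  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ValueError(
                "segmenter backend needs a registered segmenter "
                "(register_segmenter) or the optional jieba dependency"
            ) from exc
        return [t for t in jieba.cut(text) if t.strip()]  # pragma: no cover
    raise ValueError(f"unknown tokenize backend {backend!r}")


# --- I/O --------------------------------------------------------------------

_FIELDS = ("id", "role", "parent_id", "title", "body", "reply_count", "like_count")


def _escape_cell(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape_cell(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"n": "\n", "t": "\t", "\\": "\\"}.get(nxt, c + nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _post_to_record(post: Post) -> dict:
    return {k: getattr(post, k) for k in _FIELDS}


def _record_to_post(rec: dict, where: str) -> Post:
    try:
        return Post(
            id=str(rec["id"]),
            role=str(rec["role"]),
            parent_id=str(rec.get("parent_id", "") or ""),
            title=str(rec.get("title", "") or ""),
            body=str(rec.get("body", "") or ""),
            reply_count=int(rec.get("reply_count", 0) or 0),
            like_count=int(rec.get("like_count", 0) or 0),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise CorpusFormatError(f"malformed record at {where}: {exc}") from exc


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus.

    ``jsonl``: one JSON object per line with the Post fields.  ``tables``:
    ``path`` is a directory holding ``questions.tsv`` and ``answers.tsv`` with
    the same field names in a header row.
    """
    path = Path(path)
    if format == "jsonl":
        posts = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"malformed record at line {lineno}: {exc}") from exc
                posts.append(_record_to_post(rec, f"line {lineno}"))
        return Corpus(posts)
    if format == "tables":
        posts = []
        for name in ("questions.tsv", "answers.tsv"):
            table = path / name
            if not table.exists():
                raise CorpusFormatError(f"missing table {table}")
            with table.open(encoding="utf-8") as fh:
                header = fh.readline().rstrip("\n").split("\t")
                for lineno, line in enumerate(fh, start=2):
                    if not line.strip():
                        continue
                    values = line.rstrip("\n").split("\t")
                    if len(values) != len(header):
                        raise CorpusFormatError(
                            f"malformed record at {name} line {lineno}: "
                            f"{len(values)} fields, expected {len(header)}"
                        )
                    rec = dict(zip(header, values))
                    for key in ("body", "title"):
                        rec[key] = _unescape_cell(rec.get(key, ""))
                    posts.append(_record_to_post(rec, f"{name} line {lineno}"))
        return Corpus(posts)
    raise ValueError(f"unknown corpus format {format!r}")


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus so that ``read_corpus`` round-trips it field-for-field."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for post in corpus.posts:
                fh.write(json.dumps(_post_to_record(post), ensure_ascii=False) + "\n")
        return
    if format == "tables":
        path.mkdir(parents=True, exist_ok=True)
        for name, role in (("questions.tsv", "question"), ("answers.tsv", "answer")):
            with (path / name).open("w", encoding="utf-8") as fh:
                fh.write("\t".join(_FIELDS) + "\n")
                for post in corpus.posts:
                    if post.role != role:
                        continue
                    rec = _post_to_record(post)
                    rec["body"] = _escape_cell(rec["body"])
                    rec["title"] = _escape_cell(rec["title"])
                    fh.write("\t".join(str(rec[k]) for k in _FIELDS) + "\n")
        return
    raise ValueError(f"unknown corpus format {format!r}")
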
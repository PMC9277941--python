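"""Corpus loading, preprocessing and round-tripping.

A :class:`Corpus` is an ordered collection of documents with a shared
vocabulary.  Preprocessing applies a fixed cleaning chain -- punctuation
removal, lowercasing, whitespace tokenization, short-token and stopword
removal, Porter stemming -- and drops documents left without any tokens
(downstream probability tables divide by per-document sums, so zero-token
documents would be 0/0).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .exceptions import EmptyCorpusError, InputError, StateError
from .porter import stem as porter_stem

logger = logging.getLogger(__name__)

# Punctuation and symbols are replaced by spaces before tokenization:
# everything that is neither a word character nor whitespace, plus the
# underscore.  Digits are kept.
_PUNCT_RE = re.compile(r"[^\w\s]|_")


@dataclass
class Document:
    """One document: an opaque id, its raw text, and (after preprocessing)
    the ordered list of normalized tokens."""

    doc_id: str
    raw_text: str = ""
    tokens: list[str] = field(default_factory=list)


@dataclass
class Corpus:
    """Ordered documents plus the shared vocabulary (sorted unique tokens)."""

    documents: list[Document] = field(default_factory=list)
    vocabulary: list[str] = field(default_factory=list)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    @property
    def vocab_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.vocabulary)}

    def is_processed(self) -> bool:
        return bool(self.documents) and all(d.tokens for d in self.documents)

    def __len__(self) -> int:
        return len(self.documents)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Read a stopword file (one word per line, '#' comments).

    With ``path=None`` the bundled English list is used.
    """
    if path is None:
        text = (
            resources.files("mkftm").joinpath("data/stopwords_en.txt").read_text("utf-8")
        )
    else:
        p = Path(path)
        if not p.is_file():
            raise InputError(f"stopword file not found: {p}")
        text = p.read_text("utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


@dataclass
class PreprocessConfig:
    """Knobs of the text-cleaning chain.

    ``stopwords=None`` selects the bundled English list; pass a set of
    strings (possibly empty) or a file path to override.
    """

    lowercase: bool = True
    strip_punctuation: bool = True
    min_token_length: int = 3
    stopwords: frozenset[str] | set[str] | str | Path | None = None
    stem: bool = True

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise InputError("min_token_length must be >= 1")

    def resolved_stopwords(self) -> frozenset[str]:
        if self.stopwords is None:
            return load_stopwords()
        if isinstance(self.stopwords, (str, Path)):
            return load_stopwords(self.stopwords)
        return frozenset(self.stopwords)


def load_corpus(source: str | Path, format: str = "lines") -> Corpus:
    """Read raw documents from ``source``.

    ``format="lines"``: one document per line, doc_id = 0-based line index.
    ``format="directory"``: each ``*.txt`` file is one document in
    lexicographic filename order, doc_id = filename stem.
    Tokens and vocabulary are left empty; run :func:`preprocess` next.
    """
    src = Path(source)
    if format == "lines":
        if not src.is_file():
            raise InputError(f"corpus file not found: {src}")
        lines = src.read_text("utf-8").splitlines()
        docs = [Document(doc_id=str(i), raw_text=line) for i, line in enumerate(lines)]
    elif format == "directory":
        if not src.is_dir():
            raise InputError(f"corpus directory not found: {src}")
        files = sorted(src.glob("*.txt"), key=lambda p: p.name)
        docs = [Document(doc_id=f.stem, raw_text=f.read_text("utf-8")) for f in files]
    else:
        raise InputError(f"unknown corpus format: {format!r}")
    if not docs:
        raise EmptyCorpusError(f"no documents found in {src}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise InputError(f"duplicate doc_id: {d.doc_id!r}")
        seen.add(d.doc_id)
    return Corpus(documents=docs)


def _clean_tokens(text: str, cfg: PreprocessConfig, stopwords: frozenset[str]) -> list[str]:
    if cfg.strip_punctuation:
        text = _PUNCT_RE.sub(" ", text)
    if cfg.lowercase:
        text = text.lower()
    tokens = text.split()
    tokens = [t for t in tokens if len(t) >= cfg.min_token_length]
    tokens = [t for t in tokens if t not in stopwords]
    if cfg.stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def preprocess(corpus: Corpus, config: PreprocessConfig | None = None) -> Corpus:
    """Apply the cleaning chain and rebuild the vocabulary.

    The chain runs in a fixed order: strip punctuation -> lowercase ->
    whitespace tokenize -> drop tokens shorter than ``min_token_length`` ->
    drop stopwords -> Porter stem.  Documents with no surviving tokens are
    dropped (their ids are logged).  The input corpus is not mutated.
    """
    cfg = config or PreprocessConfig()
    stopwords = cfg.resolved_stopwords()
    kept: list[Document] = []
    dropped: list[str] = []
    for doc in corpus.documents:
        tokens = _clean_tokens(doc.raw_text, cfg, stopwords)
        if tokens:
            kept.append(Document(doc.doc_id, doc.raw_text, tokens))
        else:
            dropped.append(doc.doc_id)
    if dropped:
        logger.info("preprocess dropped %d empty documents: %s", len(dropped), dropped)
    if not kept:
        logger.warning("preprocess produced an empty corpus")
    vocab = sorted({t for d in kept for t in d.tokens})
    return Corpus(documents=kept, vocabulary=vocab)


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a processed corpus as TSV: doc_id <TAB> space-joined tokens."""
    if not corpus.is_processed():
        raise StateError("cannot save an unprocessed corpus")
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(f"{d.doc_id}\t{' '.join(d.tokens)}\n")


def load_processed_corpus(path: str | Path) -> Corpus:
    """Read a TSV written by :func:`save_corpus` back into a Corpus."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"corpus file not found: {p}")
    docs: list[Document] = []
    for line in p.read_text("utf-8").splitlines():
        if not line.strip():
            continue
        doc_id, _, toks = line.partition("\t")
        tokens = toks.split()
        docs.append(Document(doc_id=doc_id, raw_text=toks, tokens=tokens))
    if not docs:
        raise EmptyCorpusError(f"no documents found in {p}")
    vocab = sorted({t for d in docs for t in d.tokens})
    return Corpus(documents=docs, vocabulary=vocab)


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a doc_id <TAB> label file into a dict."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"labels file not found: {p}")
    labels: dict[str, str] = {}
    for line in p.read_text("utf-8").splitlines():
        if not line.strip():
            continue
        doc_id, _, label = line.partition("\t")
        labels[doc_id] = label.strip()
    return labels
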
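"""Synthetic corpora with planted topic structure.

Documents are drawn from a Dirichlet-multinomial mixture: each planted
topic is a probability distribution over the vocabulary (by default the
vocabulary is partitioned into disjoint per-topic supports and a sharp
Dirichlet is drawn within each block), each document draws a topic
mixture from a symmetric Dirichlet and then samples its tokens
topic-by-topic.  Redundancy -- the near-duplicate documents that plague
real biomedical corpora -- is emulated by duplicating a fraction of the
documents with random token dropout.

The generator emits pre-tokenized documents (synthetic words
``w0000 ...``) so clustering behavior can be tested independently of
stemming; the token strings survive the full preprocessing chain
unchanged, so the same corpora also exercise the text path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .corpus import Corpus, Document
from .exceptions import ConfigError
from .topic_model import TopicModel


@dataclass
class SyntheticSpec:
    """Study conditions of the generator.

    ``topic_sharpness`` is the Dirichlet concentration of the per-topic
    word distributions (lower = sharper, fewer effective words);
    ``doc_topic_concentration`` plays the same role for per-document
    topic mixtures (lower = purer documents).
    """

    K_true: int = 5
    vocab_size: int = 500
    n_docs: int = 200
    doc_length_mean: float = 60.0
    topic_sharpness: float = 0.05
    doc_topic_concentration: float = 0.08
    redundancy_rate: float = 0.0
    dropout_rate: float = 0.1
    disjoint_supports: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 2:
            raise ConfigError("K_true must be >= 2")
        if self.vocab_size < self.K_true:
            raise ConfigError("vocab_size must be >= K_true (one support word per topic)")
        if self.n_docs < 1 or self.doc_length_mean <= 0:
            raise ConfigError("n_docs and doc_length_mean must be positive")
        if self.topic_sharpness <= 0 or self.doc_topic_concentration <= 0:
            raise ConfigError("Dirichlet concentrations must be > 0")
        if not 0 <= self.redundancy_rate <= 1 or not 0 <= self.dropout_rate <= 1:
            raise ConfigError("rates must lie in [0, 1]")


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its ground truth."""

    corpus: Corpus
    vocab: list[str]  # full generator vocabulary (w0000 ... ), sorted
    planted_topic_word: np.ndarray  # (K_true, vocab_size), rows sum to 1
    planted_doc_topic: np.ndarray  # (n_total, K_true), rows sum to 1
    planted_labels: np.ndarray  # argmax topic per document (incl. duplicates)
    duplicate_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def K_true(self) -> int:
        return self.planted_topic_word.shape[0]


def _topic_word_distributions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    m, K = spec.vocab_size, spec.K_true
    table = np.zeros((K, m))
    if spec.disjoint_supports:
        bounds = np.linspace(0, m, K + 1).astype(int)
        for k in range(K):
            block = slice(bounds[k], bounds[k + 1])
            size = bounds[k + 1] - bounds[k]
            table[k, block] = rng.dirichlet(np.full(size, spec.topic_sharpness))
    else:
        for k in range(K):
            table[k] = rng.dirichlet(np.full(m, spec.topic_sharpness))
    # numerical underflow in a sharp Dirichlet can zero a row; repair to uniform
    for k in range(K):
        s = table[k].sum()
        if s <= 0:
            table[k] = 1.0 / m
        else:
            table[k] /= s
    return table


def generate(spec: SyntheticSpec) -> SyntheticCorpus:
    """Draw a corpus under the spec; fully reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    m, K = spec.vocab_size, spec.K_true
    width = max(4, len(str(m - 1)))
    vocab = [f"w{i:0{width}d}" for i in range(m)]
    topic_word = _topic_word_distributions(spec, rng)
    doc_topic = rng.dirichlet(np.full(K, spec.doc_topic_concentration), size=spec.n_docs)

    docs: list[Document] = []
    for j in range(spec.n_docs):
        length = max(1, int(rng.poisson(spec.doc_length_mean)))
        topic_counts = rng.multinomial(length, doc_topic[j])
        tokens: list[str] = []
        for k in range(K):
            if topic_counts[k] == 0:
                continue
            word_counts = rng.multinomial(topic_counts[k], topic_word[k])
            for w in np.nonzero(word_counts)[0]:
                tokens.extend([vocab[w]] * word_counts[w])
        perm = rng.permutation(len(tokens))
        tokens = [tokens[i] for i in perm]
        docs.append(Document(doc_id=f"d{j:04d}", raw_text=" ".join(tokens), tokens=tokens))

    labels = list(np.argmax(doc_topic, axis=1))
    mixtures = list(doc_topic)
    duplicate_map: dict[str, list[str]] = {}
    n_dup = int(np.floor(spec.redundancy_rate * spec.n_docs))
    if n_dup > 0:
        chosen = rng.choice(spec.n_docs, size=n_dup, replace=False)
        for c, j in enumerate(chosen):
            src = docs[j]
            keep = rng.random(len(src.tokens)) >= spec.dropout_rate
            tokens = [t for t, k in zip(src.tokens, keep) if k]
            if not tokens:
                tokens = [src.tokens[int(rng.integers(len(src.tokens)))]]
            dup_id = f"{src.doc_id}_dup{c}"
            docs.append(Document(doc_id=dup_id, raw_text=" ".join(tokens), tokens=tokens))
            duplicate_map.setdefault(src.doc_id, []).append(dup_id)
            labels.append(labels[j])
            mixtures.append(mixtures[j])

    used_vocab = sorted({t for d in docs for t in d.tokens})
    corpus = Corpus(documents=docs, vocabulary=used_vocab)
    return SyntheticCorpus(
        corpus=corpus,
        vocab=vocab,
        planted_topic_word=topic_word,
        planted_doc_topic=np.vstack(mixtures),
        planted_labels=np.asarray(labels),
        duplicate_map=duplicate_map,
    )


def _expand_to_vocab(
    table: np.ndarray, model_vocab: list[str], full_vocab: list[str]
) -> np.ndarray:
    """Embed an (m_model, K) table into the generator's vocabulary space."""
    index = {t: i for i, t in enumerate(full_vocab)}
    out = np.zeros((len(full_vocab), table.shape[1]))
    for i, term in enumerate(model_vocab):
        if term in index:
            out[index[term]] = table[i]
    return out


def _greedy_match(cosine: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching on a (recovered x planted) cosine matrix."""
    C = cosine.copy()
    matches = []
    for _ in range(min(C.shape)):
        r, p = np.unravel_index(np.argmax(C), C.shape)
        matches.append((int(r), int(p), float(C[r, p])))
        C[r, :] = -np.inf
        C[:, p] = -np.inf
    return matches


def score_recovery(model: TopicModel, truth: SyntheticCorpus) -> dict:
    """Compare a fitted model with the planted structure.

    Topics are matched greedily by maximal cosine between word
    distributions (each planted topic used once); documents are scored
    by the adjusted Rand index between argmax-topic assignments and the
    planted labels.  Both scores are invariant to topic relabeling.
    """
    if model.K != truth.K_true:
        raise ConfigError(f"model K={model.K} differs from planted K={truth.K_true}")
    rec = _expand_to_vocab(model.P_W_given_T, model.vocabulary, truth.vocab)  # (m, K)
    planted = truth.planted_topic_word.T  # (m, K)
    rn = np.linalg.norm(rec, axis=0)
    pn = np.linalg.norm(planted, axis=0)
    cosine = (rec.T @ planted) / np.outer(np.maximum(rn, 1e-300), np.maximum(pn, 1e-300))
    matches = _greedy_match(cosine)
    mean_cosine = float(np.mean([c for _, _, c in matches]))

    label_by_id = dict(zip(truth.corpus.doc_ids, truth.planted_labels))
    true_labels = [label_by_id[d] for d in model.doc_ids]
    pred = np.argmax(model.P_T_given_D, axis=1)
    ari = float(adjusted_rand_score(true_labels, pred))
    return {
        "mean_matched_cosine": mean_cosine,
        "ari": ari,
        "matching": [(r, p) for r, p, _ in matches],
        "matched_cosines": [c for _, _, c in matches],
    }


def planted_supports(truth: SyntheticCorpus, top: int = 10) -> list[list[str]]:
    """The ``top`` highest-probability words of each planted topic."""
    out = []
    for k in range(truth.K_true):
        order = np.argsort(-truth.planted_topic_word[k], kind="stable")
        out.append([truth.vocab[i] for i in order[:top]])
    return out


def write_synthetic(truth: SyntheticCorpus, corpus_path: str | Path,
                    truth_path: str | Path | None = None) -> None:
    """Write the corpus one-document-per-line (readable by corpus loading)
    plus an optional JSON ground-truth sidecar."""
    with open(corpus_path, "w", encoding="utf-8") as fh:
        for d in truth.corpus.documents:
            fh.write(" ".join(d.tokens) + "\n")
    if truth_path is not None:
        payload = {
            "vocab": truth.vocab,
            "doc_ids": truth.corpus.doc_ids,
            "planted_topic_word": truth.planted_topic_word.tolist(),
            "planted_doc_topic": truth.planted_doc_topic.tolist(),
            "planted_labels": truth.planted_labels.tolist(),
            "duplicate_map": truth.duplicate_map,
        }
        Path(truth_path).write_text(json.dumps(payload) + "\n", "utf-8")
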
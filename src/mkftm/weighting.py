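"""Bag-of-words counting and global term weighting (FP-IDF).

The weighted term-by-document matrix is the product of a local weight
(raw term frequency, or cosine-normalized frequency) and a global,
per-term discrimination weight.  The fusion probabilistic IDF (FP-IDF)
global weight is

    fp_idf(t) = log( M * N * (N - df_t) / df_t^2 )

where ``N`` is the number of documents, ``df_t`` the document frequency
of term ``t`` and ``M`` the maximum document frequency over the
vocabulary.  By the product rule of logarithms this is exactly the sum
of a hybrid IDF, ``log(M * N / df_t)``, and a probabilistic IDF,
``log((N - df_t) / df_t)``.  Terms occurring in every document would
make the ``N - df_t`` factor log(0); that factor is guarded with a small
epsilon (1 / 2N) inside the log, and global weights are floored at zero
before multiplication so the weighted matrix stays nonnegative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .corpus import Corpus
from .exceptions import ConfigError, DegenerateInputError, EmptyCorpusError, StateError

LOCAL_SCHEMES = ("raw_tf", "cosine_normalized")
GLOBAL_SCHEMES = ("none", "fp_idf", "hybrid_idf", "prob_idf")


@dataclass
class DocTermMatrix:
    """Sparse term-by-document count matrix (rows = terms, cols = documents)."""

    counts: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return self.counts.shape[1]


@dataclass
class GlobalStats:
    """Per-term corpus statistics feeding the global weights."""

    F: np.ndarray  # overall frequency, sum of tf over documents
    df: np.ndarray  # document frequency n_t
    M: int  # max document frequency over the vocabulary
    N: int  # number of documents


@dataclass
class WeightedMatrix:
    """Nonnegative term-by-document matrix after local x global weighting."""

    values: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]
    local_scheme: str = "raw_tf"
    global_scheme: str = "none"

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]


def build_doc_term_matrix(corpus: Corpus) -> DocTermMatrix:
    """Count term occurrences per document into a sparse matrix."""
    if not corpus.documents:
        raise EmptyCorpusError("empty corpus")
    if not corpus.is_processed() or not corpus.vocabulary:
        raise StateError("corpus must be preprocessed before counting")
    index = corpus.vocab_index
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for j, doc in enumerate(corpus.documents):
        for tok, c in Counter(doc.tokens).items():
            rows.append(index[tok])
            cols.append(j)
            data.append(c)
    counts = sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(corpus.vocabulary), len(corpus.documents)),
        dtype=np.int64,
    )
    return DocTermMatrix(counts=counts, vocabulary=list(corpus.vocabulary), doc_ids=corpus.doc_ids)


def cosine_normalize_documents(dtm: DocTermMatrix) -> WeightedMatrix:
    """Scale each document column to unit Euclidean norm."""
    counts = dtm.counts.astype(float)
    norms = np.sqrt(np.asarray(counts.multiply(counts).sum(axis=0)).ravel())
    if np.any(norms == 0):
        raise DegenerateInputError("document column with zero norm")
    values = (counts @ sp.diags(1.0 / norms)).tocsr()
    return WeightedMatrix(values, dtm.vocabulary, dtm.doc_ids, "cosine_normalized", "none")


def global_frequency(dtm: DocTermMatrix) -> GlobalStats:
    """Overall frequency F, document frequency df, and M = max df."""
    F = np.asarray(dtm.counts.sum(axis=1)).ravel()
    df = np.asarray((dtm.counts > 0).sum(axis=1)).ravel()
    return GlobalStats(F=F, df=df, M=int(df.max()), N=dtm.N)


def term_probability(dtm: DocTermMatrix) -> sp.csr_matrix:
    """Row-normalize counts: P_ij = tf_ij / sum_j tf_ij."""
    row_sums = np.asarray(dtm.counts.sum(axis=1)).ravel().astype(float)
    if np.any(row_sums == 0):
        raise DegenerateInputError("term row with zero total frequency")
    return (sp.diags(1.0 / row_sums) @ dtm.counts.astype(float)).tocsr()


def _to_base(x: np.ndarray, base: float | None) -> np.ndarray:
    return x if base is None else x / np.log(base)


def _guarded_rarity(df: np.ndarray, N: int) -> np.ndarray:
    """(N - df) with the df = N boundary guarded by epsilon = 1/(2N)."""
    eps = 1.0 / (2.0 * N)
    return np.maximum(N - df.astype(float), eps)


def hybrid_idf(stats: GlobalStats, base: float | None = None) -> np.ndarray:
    """log(M * N / df_t) per term (natural log by default)."""
    if np.any(stats.df < 1):
        raise DegenerateInputError("df must be >= 1 for every term")
    return _to_base(np.log(float(stats.M) * stats.N / stats.df), base)


def probabilistic_idf(stats: GlobalStats, base: float | None = None) -> np.ndarray:
    """log((N - df_t) / df_t), guarded at df_t = N."""
    if np.any(stats.df < 1):
        raise DegenerateInputError("df must be >= 1 for every term")
    return _to_base(np.log(_guarded_rarity(stats.df, stats.N) / stats.df), base)


def fp_idf(stats: GlobalStats, base: float | None = None) -> np.ndarray:
    """log(M * N * (N - df_t) / df_t^2), the fusion of the two IDFs.

    Equals ``hybrid_idf + probabilistic_idf`` elementwise (the log of the
    product of the two arguments), with the same boundary guard at
    df_t = N.
    """
    if np.any(stats.df < 1):
        raise DegenerateInputError("df must be >= 1 for every term")
    df = stats.df.astype(float)
    return _to_base(
        np.log(float(stats.M) * stats.N * _guarded_rarity(stats.df, stats.N) / df**2),
        base,
    )


def _local_matrix(dtm: DocTermMatrix, local_scheme: str) -> sp.csr_matrix:
    if local_scheme == "raw_tf":
        return dtm.counts.astype(float).tocsr()
    if local_scheme == "cosine_normalized":
        return cosine_normalize_documents(dtm).values
    raise ConfigError(f"unknown local scheme: {local_scheme!r}")


def apply_weights(
    dtm: DocTermMatrix,
    local_scheme: str = "raw_tf",
    global_scheme: str = "fp_idf",
    per_document_max: bool = False,
    base: float | None = None,
) -> WeightedMatrix:
    """Combine local and global weights into the weighted matrix.

    values[i, j] = local(i, j) * max(global(i), 0).  Global weights are
    floored at zero so the result is nonnegative and usable as an
    unnormalized probability table; the sparsity pattern of the counts is
    preserved (up to rows whose global weight is zero).

    ``per_document_max=True`` replaces the corpus-level M with a
    per-document maximum over the terms occurring in that document,
    turning the global weight into a per-term-per-document quantity
    (only meaningful for the fp_idf / hybrid_idf schemes).
    """
    local = _local_matrix(dtm, local_scheme)
    stats = global_frequency(dtm)
    if per_document_max:
        if global_scheme not in ("fp_idf", "hybrid_idf"):
            raise ConfigError("per_document_max requires fp_idf or hybrid_idf")
        values = _per_document_weights(dtm, local, stats, global_scheme, base)
        return WeightedMatrix(values, dtm.vocabulary, dtm.doc_ids, local_scheme, global_scheme)
    if global_scheme == "none":
        g = np.ones(dtm.m)
    elif global_scheme == "fp_idf":
        g = fp_idf(stats, base)
    elif global_scheme == "hybrid_idf":
        g = hybrid_idf(stats, base)
    elif global_scheme == "prob_idf":
        g = probabilistic_idf(stats, base)
    else:
        raise ConfigError(f"unknown global scheme: {global_scheme!r}")
    g = np.maximum(g, 0.0)
    values = (sp.diags(g) @ local).tocsr()
    values.eliminate_zeros()
    return WeightedMatrix(values, dtm.vocabulary, dtm.doc_ids, local_scheme, global_scheme)


def _per_document_weights(
    dtm: DocTermMatrix,
    local: sp.csr_matrix,
    stats: GlobalStats,
    global_scheme: str,
    base: float | None,
) -> sp.csr_matrix:
    csc = local.tocsc()
    counts_csc = dtm.counts.tocsc()
    rarity = _guarded_rarity(stats.df, stats.N)
    df = stats.df.astype(float)
    out = csc.copy().astype(float)
    for j in range(dtm.N):
        terms = counts_csc.indices[counts_csc.indptr[j] : counts_csc.indptr[j + 1]]
        if terms.size == 0:
            continue
        Mj = float(stats.df[terms].max())
        if global_scheme == "fp_idf":
            g = np.log(Mj * stats.N * rarity[terms] / df[terms] ** 2)
        else:
            g = np.log(Mj * stats.N / df[terms])
        g = np.maximum(_to_base(g, base), 0.0)
        sl = slice(csc.indptr[j], csc.indptr[j + 1])
        out.data[sl] = csc.data[sl] * g
    out = out.tocsr()
    out.eliminate_zeros()
    return out


def save_matrix(matrix: DocTermMatrix | WeightedMatrix, prefix: str | Path) -> None:
    """Write the sparse matrix (MatrixMarket) plus vocabulary/doc sidecars."""
    prefix = Path(prefix)
    values = matrix.counts if isinstance(matrix, DocTermMatrix) else matrix.values
    scipy.io.mmwrite(str(prefix) + ".mtx", values)
    Path(str(prefix) + ".terms.txt").write_text(
        "".join(t + "\n" for t in matrix.vocabulary), "utf-8"
    )
    Path(str(prefix) + ".docs.txt").write_text(
        "".join(d + "\n" for d in matrix.doc_ids), "utf-8"
    )


def load_weighted_matrix(prefix: str | Path) -> WeightedMatrix:
    """Read a matrix written by :func:`save_matrix`."""
    prefix = Path(prefix)
    values = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    vocab = Path(str(prefix) + ".terms.txt").read_text("utf-8").splitlines()
    docs = Path(str(prefix) + ".docs.txt").read_text("utf-8").splitlines()
    return WeightedMatrix(values, vocab, docs)
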
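"""Probabilistic topic tables and the end-to-end MKFTM fit.

The fuzzy membership matrix of the clustering is read as P(T|D): each
cluster is a topic and each document distributes over topics.  Combined
with the weighted term-by-document matrix this yields

    P(D_j)        column mass of the weighted matrix, normalized
    P(D_j, T_k) = P(T_k | D_j) * P(D_j)
    P(D_j | T_k)  the joint, normalized per topic column
    P(W_i | D_j)  the weighted matrix, normalized per document column
    P(W_i | T_k) = sum_j P(W_i | D_j) * P(D_j | T_k)

All probabilities come from the pre-PCA weighted matrix (nonnegative);
PCA feeds only the clustering geometry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import mkfcm, reduction, weighting
from .corpus import Corpus, PreprocessConfig, preprocess
from .exceptions import ConfigError, DegenerateInputError, EmptyCorpusError, InputError, StateError

logger = logging.getLogger(__name__)


@dataclass
class TopicModel:
    """The five probability tables of a fitted topic model."""

    K: int
    P_D: np.ndarray  # (n,)
    P_T_given_D: np.ndarray  # (n, K) row-stochastic
    P_D_joint_T: np.ndarray  # (n, K)
    P_D_given_T: np.ndarray  # (n, K) column-stochastic
    P_W_given_D: sp.csr_matrix  # (m, n) column-stochastic
    P_W_given_T: np.ndarray  # (m, K) column-stochastic
    vocabulary: list[str]
    doc_ids: list[str]
    meta: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Configuration of the full fit: preprocessing, weighting scheme,
    PCA retention, and clustering hyperparameters."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    local_scheme: str = "raw_tf"
    global_scheme: str = "fp_idf"
    pca_components: int | float = 0.95
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    kernels: list[mkfcm.KernelSpec] | None = None
    seed: int = 0


def document_probabilities(weighted: weighting.WeightedMatrix) -> np.ndarray:
    """P(D_j): share of total weighted mass carried by each document."""
    col = np.asarray(weighted.values.sum(axis=0)).ravel()
    total = col.sum()
    if total <= 0:
        raise DegenerateInputError("weighted matrix has zero total mass")
    return col / total


def topic_document_distribution(
    P_T_given_D: np.ndarray, P_D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Joint P(D, T) and per-topic-normalized P(D|T).

    A topic with zero joint mass keeps a uniform column (with a logged
    warning) so K is preserved.
    """
    joint = P_T_given_D * P_D[:, None]
    col = joint.sum(axis=0)
    n = joint.shape[0]
    P_D_given_T = np.empty_like(joint)
    for k in range(joint.shape[1]):
        if col[k] > 0:
            P_D_given_T[:, k] = joint[:, k] / col[k]
        else:
            logger.warning("topic %d has zero joint mass; uniform P(D|T) column", k)
            P_D_given_T[:, k] = 1.0 / n
    return joint, P_D_given_T


def word_document_distribution(weighted: weighting.WeightedMatrix) -> sp.csr_matrix:
    """P(W|D): the weighted matrix with each document column normalized."""
    col = np.asarray(weighted.values.sum(axis=0)).ravel()
    if np.any(col <= 0):
        raise DegenerateInputError("document column with zero weighted mass")
    return (weighted.values @ sp.diags(1.0 / col)).tocsr()


def word_topic_distribution(
    P_W_given_D: sp.csr_matrix | np.ndarray, P_D_given_T: np.ndarray
) -> np.ndarray:
    """P(W|T) = P(W|D) . P(D|T), mixing document word distributions."""
    pwd = P_W_given_D
    if pwd.shape[1] != P_D_given_T.shape[0]:
        raise StateError("document dimensions of P(W|D) and P(D|T) disagree")
    out = pwd @ P_D_given_T
    return np.asarray(out)


def build_topic_model(
    weighted: weighting.WeightedMatrix,
    membership: np.ndarray,
    meta: dict | None = None,
) -> TopicModel:
    """Assemble all probability tables from the weighted matrix and the
    fuzzy membership matrix (read as P(T|D))."""
    P_D = document_probabilities(weighted)
    joint, P_D_given_T = topic_document_distribution(membership, P_D)
    P_W_given_D = word_document_distribution(weighted)
    P_W_given_T = word_topic_distribution(P_W_given_D, P_D_given_T)
    return TopicModel(
        K=membership.shape[1],
        P_D=P_D,
        P_T_given_D=membership,
        P_D_joint_T=joint,
        P_D_given_T=P_D_given_T,
        P_W_given_D=P_W_given_D,
        P_W_given_T=P_W_given_T,
        vocabulary=list(weighted.vocabulary),
        doc_ids=list(weighted.doc_ids),
        meta=meta or {},
    )


def fit_mkftm(
    corpus: Corpus,
    K: int,
    config: PipelineConfig | None = None,
    validate: bool = False,
) -> TopicModel:
    """Run the full pipeline: preprocess -> counts -> weighting -> PCA ->
    multiple-kernel fuzzy clustering -> probability tables.

    A corpus whose documents already carry tokens (e.g. the synthetic
    generator's output) skips the text-cleaning step.
    """
    if K < 2:
        raise ConfigError("K must be >= 2")
    cfg = config or PipelineConfig()
    if not corpus.documents:
        raise EmptyCorpusError("empty corpus")
    if corpus.is_processed():
        processed = corpus
    else:
        processed = preprocess(corpus, cfg.preprocess)
        if not processed.documents:
            raise EmptyCorpusError("all documents were empty after preprocessing")
    if len(processed) < K:
        raise ConfigError(f"need at least K={K} documents, have {len(processed)}")
    dtm = weighting.build_doc_term_matrix(processed)
    wm = weighting.apply_weights(dtm, cfg.local_scheme, cfg.global_scheme)
    red = reduction.reduce(wm, cfg.pca_components)
    mk_cfg = mkfcm.MKFCMConfig(
        n_clusters=K,
        fuzzifier=cfg.fuzzifier,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
        kernels=cfg.kernels,
        validate=validate,
    )
    result = mkfcm.fit(red.scores, mk_cfg)
    if not result.converged:
        logger.warning("clustering hit max_iter=%d without converging", cfg.max_iter)
    meta = {
        "seed": cfg.seed,
        "K": K,
        "local_scheme": cfg.local_scheme,
        "global_scheme": cfg.global_scheme,
        "pca_components_retained": red.r,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "kernel_weights": [float(z) for z in result.kernel_weights],
        "kernel_params": result.kernel_params,
        "membership_change_trace": [float(d) for d in result.membership_change_trace],
        "n_documents": len(processed),
        "n_terms": dtm.m,
    }
    return build_topic_model(wm, result.membership, meta)


def top_words(model: TopicModel, topic: int, count: int) -> list[str]:
    """The ``count`` highest-probability words of a topic; ties break by
    vocabulary order."""
    if not 0 <= topic < model.K:
        raise InputError(f"topic {topic} out of range [0, {model.K})")
    if not 1 <= count <= len(model.vocabulary):
        raise InputError(f"count {count} out of range [1, {len(model.vocabulary)}]")
    order = np.argsort(-model.P_W_given_T[:, topic], kind="stable")
    return [model.vocabulary[i] for i in order[:count]]


# ---------------------------------------------------------------------------
# Serialization: a model directory with JSON metadata and TSV tables.

def _topic_cols(K: int) -> list[str]:
    return [f"topic_{k}" for k in range(K)]


def save_topic_model(model: TopicModel, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metadata.json").write_text(
        json.dumps({"K": model.K, **model.meta}, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    (out / "vocabulary.txt").write_text("".join(t + "\n" for t in model.vocabulary), "utf-8")
    (out / "doc_ids.txt").write_text("".join(d + "\n" for d in model.doc_ids), "utf-8")
    cols = _topic_cols(model.K)
    pd.DataFrame({"doc_id": model.doc_ids, "p": model.P_D}).to_csv(
        out / "p_d.tsv", sep="\t", index=False
    )
    for name, table in (
        ("p_t_given_d", model.P_T_given_D),
        ("p_d_joint_t", model.P_D_joint_T),
        ("p_d_given_t", model.P_D_given_T),
    ):
        df = pd.DataFrame(table, columns=cols)
        df.insert(0, "doc_id", model.doc_ids)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    wt = pd.DataFrame(model.P_W_given_T, columns=cols)
    wt.insert(0, "term", model.vocabulary)
    wt.to_csv(out / "p_w_given_t.tsv", sep="\t", index=False)
    wd = pd.DataFrame(np.asarray(model.P_W_given_D.todense()), columns=model.doc_ids)
    wd.insert(0, "term", model.vocabulary)
    wd.to_csv(out / "p_w_given_d.tsv", sep="\t", index=False)


def load_topic_model(indir: str | Path) -> TopicModel:
    src = Path(indir)
    if not src.is_dir():
        raise InputError(f"model directory not found: {src}")
    meta = json.loads((src / "metadata.json").read_text("utf-8"))
    K = int(meta.pop("K"))
    vocabulary = (src / "vocabulary.txt").read_text("utf-8").splitlines()
    doc_ids = (src / "doc_ids.txt").read_text("utf-8").splitlines()
    cols = _topic_cols(K)
    P_D = pd.read_csv(src / "p_d.tsv", sep="\t")["p"].to_numpy()
    tables = {}
    for name in ("p_t_given_d", "p_d_joint_t", "p_d_given_t"):
        tables[name] = pd.read_csv(src / f"{name}.tsv", sep="\t")[cols].to_numpy()
    P_W_given_T = pd.read_csv(src / "p_w_given_t.tsv", sep="\t")[cols].to_numpy()
    wd = pd.read_csv(src / "p_w_given_d.tsv", sep="\t")
    P_W_given_D = sp.csr_matrix(wd[[str(d) for d in doc_ids]].to_numpy())
    return TopicModel(
        K=K,
        P_D=P_D,
        P_T_given_D=tables["p_t_given_d"],
        P_D_joint_T=tables["p_d_joint_t"],
        P_D_given_T=tables["p_d_given_t"],
        P_W_given_D=P_W_given_D,
        P_W_given_T=P_W_given_T,
        vocabulary=vocabulary,
        doc_ids=doc_ids,
        meta=meta,
    )
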
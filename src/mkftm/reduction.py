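"""PCA de-noising of weighted document vectors.

Documents are the observations (columns of the weighted matrix,
transposed to rows), mean-centered per term and projected onto the top
right-singular directions.  Only centering is applied -- no per-term
variance scaling, which would undo the term weighting.  Component signs
are fixed so that the largest-magnitude loading of each component is
positive, making runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import ConfigError, DegenerateInputError
from .weighting import WeightedMatrix


@dataclass
class ReducedDocuments:
    """PCA scores of the documents plus the projection that produced them."""

    scores: np.ndarray  # (n_docs, r)
    components: np.ndarray  # (n_terms, r) orthonormal loadings
    mean_vector: np.ndarray  # (n_terms,)
    explained_variance_ratio: np.ndarray  # (r,)
    doc_ids: list[str]

    @property
    def r(self) -> int:
        return self.scores.shape[1]


def reduce(
    weighted: WeightedMatrix,
    n_components: int | float = 0.95,
    max_components: int = 200,
) -> ReducedDocuments:
    """Project documents onto principal components.

    ``n_components`` may be an integer (exact number of components,
    must be <= min(n_docs - 1, n_terms)) or a fraction in (0, 1]
    (smallest r reaching that cumulative explained-variance ratio,
    capped at ``max_components``).
    """
    X = np.asarray(weighted.values.todense(), dtype=float).T  # docs x terms
    n, m = X.shape
    if n < 2:
        raise DegenerateInputError("PCA needs at least 2 documents")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    rank_cap = min(n - 1, m)
    evr_all = (S**2) / total if total > 0 else np.zeros_like(S)

    if isinstance(n_components, (int, np.integer)) and not isinstance(n_components, bool):
        r = int(n_components)
        if not 1 <= r <= rank_cap:
            raise ConfigError(
                f"n_components={r} out of range [1, {rank_cap}]"
            )
    elif isinstance(n_components, float):
        if not 0.0 < n_components <= 1.0:
            raise ConfigError("variance fraction must lie in (0, 1]")
        cum = np.cumsum(evr_all[:rank_cap])
        r = int(np.searchsorted(cum, n_components - 1e-12) + 1)
        r = min(r, max_components, rank_cap)
    else:
        raise ConfigError(f"n_components must be int or float, got {n_components!r}")

    comps = Vt[:r].copy()  # (r, m)
    scores = U[:, :r] * S[:r]
    # Deterministic sign: largest-magnitude loading of each component positive.
    for k in range(r):
        idx = int(np.argmax(np.abs(comps[k])))
        if comps[k, idx] < 0:
            comps[k] *= -1.0
            scores[:, k] *= -1.0
    return ReducedDocuments(
        scores=scores,
        components=comps.T,
        mean_vector=mean,
        explained_variance_ratio=evr_all[:r],
        doc_ids=list(weighted.doc_ids),
    )


def save_reduced(reduced: ReducedDocuments, prefix: str | Path) -> None:
    """Write scores and loadings as TSV files."""
    prefix = Path(prefix)
    with open(str(prefix) + ".scores.tsv", "w", encoding="utf-8") as fh:
        for doc_id, row in zip(reduced.doc_ids, reduced.scores):
            fh.write(doc_id + "\t" + "\t".join(repr(v) for v in row) + "\n")
    np.savetxt(str(prefix) + ".components.tsv", reduced.components, delimiter="\t")
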
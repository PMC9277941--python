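import numpy as np
import pytest
import scipy.sparse as sp

from mkftm import synthetic, topic_model
from mkftm.corpus import Corpus, Document
from mkftm.weighting import DocTermMatrix

FIXTURE_TEXTS = [
    "The patients responded to the antiviral treatment within days.",
    "Bacterial infection rates declined after the vaccination campaign.",
    "Gene expression profiles were clustered across tumor samples.",
    "Clinical trials measured treatment outcomes in infected patients.",
    "Protein binding sites were predicted from sequence motifs.",
]


@pytest.fixture(scope="session")
def fixture_corpus_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("corpus") / "docs.txt"
    path.write_text("".join(t + "\n" for t in FIXTURE_TEXTS), "utf-8")
    return path


def make_corpus(token_lists, ids=None):
    """Build an already-processed corpus from explicit token lists."""
    ids = ids or [str(i) for i in range(len(token_lists))]
    docs = [
        Document(doc_id=i, raw_text=" ".join(toks), tokens=list(toks))
        for i, toks in zip(ids, token_lists)
    ]
    vocab = sorted({t for toks in token_lists for t in toks})
    return Corpus(documents=docs, vocabulary=vocab)


def make_dtm(array, vocab=None, docs=None):
    """Wrap a dense count array (terms x docs) as a DocTermMatrix."""
    arr = np.asarray(array)
    m, n = arr.shape
    return DocTermMatrix(
        counts=sp.csr_matrix(arr.astype(np.int64)),
        vocabulary=vocab or [f"t{i}" for i in range(m)],
        doc_ids=docs or [str(j) for j in range(n)],
    )


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted-topic corpus for fast unit tests."""
    spec = synthetic.SyntheticSpec(
        K_true=3, vocab_size=60, n_docs=45, doc_length_mean=30.0, seed=7
    )
    return synthetic.generate(spec)


@pytest.fixture(scope="session")
def small_model(small_truth):
    cfg = topic_model.PipelineConfig(seed=7)
    return topic_model.fit_mkftm(small_truth.corpus, 3, cfg, validate=True)


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated 2-D point clouds with planted labels."""
    rng = np.random.default_rng(11)
    a = rng.normal([0.0, 0.0], 0.3, size=(20, 2))
    b = rng.normal([6.0, 6.0], 0.3, size=(20, 2))
    X = np.vstack([a, b])
    labels = np.array([0] * 20 + [1] * 20)
    return X, labels
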
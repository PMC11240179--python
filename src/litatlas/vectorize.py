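"""Document vectorization: log-scaled TF-IDF, truncated SVD, transforms.

The TF-IDF weighting is

    X_ij = (1 + ln C_ij) * (1 + ln((1 + n) / (1 + df_j)))   if C_ij > 0,
    X_ij = 0                                                otherwise,

where C_ij counts occurrences of word j in abstract i, n is the corpus size
and df_j the number of documents containing word j; rows are then scaled to
unit l2 norm. The sparse TF-IDF matrix can be reduced with truncated SVD
(scores U·S, signs canonicalized), optionally row-normalized afterwards —
which makes Euclidean neighbor search equivalent to cosine on the raw scores.

Dense transformer vectors enter only through the ``VectorBackend`` adapter
contract; no model ships with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.feature_extraction.text import CountVectorizer

__all__ = [
    "DocTermCounts",
    "VectorSet",
    "VectorBackend",
    "tokenize_and_vocab",
    "tfidf_matrix",
    "reduce_svd",
    "transform",
    "save_vectors",
    "load_vectors",
]

DEFAULT_TOKEN_PATTERN = r"(?u)\b\w\w+\b"  # runs of >=2 word characters


@dataclass
class DocTermCounts:
    """Sparse document-term count matrix with its vocabulary."""

    matrix: sp.csr_matrix
    vocabulary: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VectorSet:
    """An n×d document representation with ids and a distance-metric tag."""

    ids: np.ndarray
    X: np.ndarray | sp.spmatrix
    metric: str = "euclidean"  # {euclidean, cosine}
    provenance: str = "tfidf"  # {tfidf, svd, backend, synthetic, embedding}

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if self.ids.shape[0] != self.X.shape[0]:
            raise ValueError("ids and X must have matching first dimension")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def dense(self) -> np.ndarray:
        return self.X.toarray() if sp.issparse(self.X) else np.asarray(self.X)


class VectorBackend(Protocol):
    """Adapter contract for external (e.g. transformer) document encoders.

    ``pooling`` selects how per-token representations are collapsed to one
    vector per document: the leading classification token ("cls"), the
    trailing separator token ("sep", often the strongest choice for kNN
    structure), or the mean over tokens ("mean").
    """

    def embed_texts(self, texts: list[str], pooling: str = "sep") -> VectorSet: ...


def tokenize_and_vocab(
    texts,
    token_pattern: str = DEFAULT_TOKEN_PATTERN,
    min_doc_count: int = 1,
) -> DocTermCounts:
    """Lowercase, tokenize and count; vocabulary sorted alphabetically.

    Raises ValueError on an empty corpus or a corpus with no valid tokens.
    """
    texts = list(texts)
    if not texts:
        raise ValueError("corpus is empty")
    cv = CountVectorizer(lowercase=True, token_pattern=token_pattern,
                         min_df=min_doc_count)
    try:
        C = cv.fit_transform(texts)
    except ValueError as err:  # sklearn: empty vocabulary
        raise ValueError(f"no tokens found in corpus: {err}") from err
    vocab = cv.get_feature_names_out().tolist()
    return DocTermCounts(matrix=C.tocsr(), vocabulary=vocab)


def tfidf_matrix(counts: DocTermCounts, ids=None) -> VectorSet:
    """Apply the log-scaled TF-IDF weighting and l2-normalize rows.

    Zeros stay zero (sparsity pattern preserved); all-zero rows are left as
    zero rather than normalized.
    """
    C = counts.matrix.tocsr().astype(np.float64)
    n = C.shape[0]
    df = np.asarray((C > 0).sum(axis=0)).ravel()
    idf = 1.0 + np.log((1.0 + n) / (1.0 + df))
    X = C.copy()
    X.data = 1.0 + np.log(X.data)
    X = (X @ sp.diags(idf)).tocsr()  # scale columns by idf
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    X = (sp.diags(inv) @ X).tocsr()  # scale rows to unit l2 norm
    if ids is None:
        ids = np.arange(n)
    return VectorSet(ids=np.asarray(ids), X=X, metric="euclidean", provenance="tfidf")


def _canonical_signs(scores: np.ndarray, components: np.ndarray):
    """Flip each component so its largest-magnitude loading is positive."""
    idx = np.argmax(np.abs(components), axis=1)
    flip = np.sign(components[np.arange(components.shape[0]), idx])
    flip[flip == 0] = 1.0
    return scores * flip[None, :], components * flip[:, None]


def reduce_svd(vectors: VectorSet, d: int, row_normalize: bool = False) -> VectorSet:
    """Project onto the top-d right singular subspace (scores U·S).

    Deterministic up to per-component sign, which is canonicalized by making
    the largest-magnitude loading of each component positive. With
    ``row_normalize`` the scores are scaled to unit l2 norm afterwards and
    the metric tag switches to cosine-equivalent Euclidean.
    """
    X = vectors.X
    max_d = min(X.shape)
    if d < 1 or d > max_d:
        raise ValueError(f"d must be in [1, {max_d}], got {d}")
    if sp.issparse(X) and d < max_d:
        U, S, Vt = svds(X.tocsr().astype(np.float64), k=d,
                        which="LM", random_state=0)
        order = np.argsort(-S)
        U, S, Vt = U[:, order], S[order], Vt[order]
    else:
        U, S, Vt = np.linalg.svd(X.toarray() if sp.issparse(X) else np.asarray(X),
                                 full_matrices=False)
        U, S, Vt = U[:, :d], S[:d], Vt[:d]
    scores = U * S
    scores, _ = _canonical_signs(scores, Vt)
    metric = vectors.metric
    if row_normalize:
        norms = np.linalg.norm(scores, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        scores = scores / norms
        metric = "euclidean"  # Euclidean on unit rows == cosine ordering
    return VectorSet(ids=vectors.ids, X=scores, metric=metric, provenance="svd")


def _dense_truncated(X: np.ndarray, d: int):
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :d], S[:d], Vt[:d]


def transform(vectors: VectorSet, mode: str = "raw", eps: float = 1e-10) -> VectorSet:
    """Center or whiten a dense vector set.

    ``centered`` subtracts column means; ``whitened`` additionally rotates and
    rescales so the sample covariance (ddof=1) is the identity. Near-zero
    variance directions are regularized by flooring singular values at
    ``eps`` times the largest.
    """
    if mode == "raw":
        return vectors
    X = vectors.dense()
    Xc = X - X.mean(axis=0, keepdims=True)
    if mode == "centered":
        return replace(vectors, X=Xc)
    if mode == "whitened":
        n = X.shape[0]
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        keep = S > eps * S.max()  # drop numerically rank-deficient directions
        Xw = U[:, keep] * np.sqrt(n - 1)
        # U has orthonormal columns and zero column means: cov(Xw) = I
        return replace(vectors, X=Xw)
    raise ValueError(f"unknown mode: {mode!r}")


# ---------------------------------------------------------------------------
# IO: Matrix Market for sparse, delimited text / raw binary for dense
# ---------------------------------------------------------------------------

def save_vectors(vectors: VectorSet, path_prefix: str) -> None:
    """Write a vector set: .mtx (sparse) or .tsv (dense) plus a JSON sidecar."""
    import scipy.io

    meta = {"n": int(vectors.n), "dim": int(vectors.dim),
            "metric": vectors.metric, "provenance": vectors.provenance,
            "ids": [str(i) for i in vectors.ids]}
    if sp.issparse(vectors.X):
        scipy.io.mmwrite(f"{path_prefix}.mtx", vectors.X)
        meta["format"] = "mtx"
    else:
        np.savetxt(f"{path_prefix}.tsv", np.asarray(vectors.X), delimiter="\t")
        meta["format"] = "tsv"
    with open(f"{path_prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh)


def load_vectors(path_prefix: str) -> VectorSet:
    import scipy.io

    with open(f"{path_prefix}.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta["format"] == "mtx":
        X = sp.csr_matrix(scipy.io.mmread(f"{path_prefix}.mtx"))
    else:
        X = np.loadtxt(f"{path_prefix}.tsv", delimiter="\t", ndmin=2)
    return VectorSet(ids=np.array(meta["ids"]), X=X,
                     metric=meta["metric"], provenance=meta["provenance"])
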
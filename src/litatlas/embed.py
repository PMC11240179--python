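"""t-SNE for large document collections: uniform kNN affinities, annealing.

This is the atlas-scale variant of t-SNE. Instead of perplexity-calibrated
Gaussian affinities, each point places weight 1/k on its k nearest neighbors
(k=10 by default); symmetrization gives p_ij = (w_j|i + w_i|j) / (2n). The
optimizer runs 2,250 iterations: during the first 250 the attractive term is
multiplied by an exaggeration factor annealed linearly from 12 down to 1
(no abrupt switch), followed by 2,000 plain iterations. Initialization is
PCA (first two principal components, scaled to a small spread) and the
learning rate defaults to n/12. Repulsion is computed exactly in O(n^2),
which is practical up to a few tens of thousands of points and serves as the
oracle for any approximate backend plugged in through the ``repulsion``
callable hook.

Because the objective is invariant to rotations and axis flips, independently
computed embeddings are aligned by exhaustively choosing the (±x, ±y) sign
pair that maximizes per-axis Pearson correlation with a reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .neighbors import exact_knn, knn_indices
from .vectorize import VectorSet

__all__ = [
    "AffinityGraph",
    "OptimizerSchedule",
    "Embedding2D",
    "build_knn_graph",
    "uniform_affinities",
    "tsne_embed",
    "align_orientation",
    "write_embedding",
    "read_embedding",
]


@dataclass
class AffinityGraph:
    """Sparse symmetric affinity matrix P summing to 1, built from a kNN graph."""

    P: sp.csr_matrix
    k: int

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def validate(self, tol: float = 1e-12) -> None:
        P = self.P
        if (P.data < 0).any():
            raise ValueError("affinities must be nonnegative")
        if abs(P.sum() - 1.0) > max(tol, 1e-12):
            raise ValueError(f"affinities must sum to 1, got {P.sum()}")
        if abs(P - P.T).max() > 1e-12:
            raise ValueError("affinity matrix must be symmetric")
        if abs(P.diagonal()).max() > 0:
            raise ValueError("affinity matrix must have zero diagonal")
        nnz = np.diff(P.indptr)
        if len(nnz) and nnz.min() < self.k:
            # each row keeps its own k out-neighbors; the upper bound is
            # k + in-degree, which exceeds 2k at hub points, so only the
            # lower bound is checked here
            raise ValueError("every row must keep its k out-neighbors")


@dataclass
class OptimizerSchedule:
    """Iteration schedule: annealed exaggeration phase, then plain descent.

    The exaggeration factor rho multiplies the attractive term; it decays
    linearly from ``rho_start`` to 1 over the first ``n_exaggeration``
    iterations and stays at 1 for the remaining ones. ``learning_rate=None``
    means n/12.
    """

    n_iter: int = 2250
    n_exaggeration: int = 250
    rho_start: float = 12.0
    learning_rate: float | None = None
    momentum_exaggeration: float = 0.5
    momentum: float = 0.8
    seed: int = 0

    def rho(self, iteration: int) -> float:
        """Exaggeration at 0-based iteration; 1 after the annealing phase."""
        if iteration >= self.n_exaggeration:
            return 1.0
        frac = iteration / self.n_exaggeration
        return self.rho_start + (1.0 - self.rho_start) * frac

    def momentum_at(self, iteration: int) -> float:
        return (self.momentum_exaggeration if iteration < self.n_exaggeration
                else self.momentum)


@dataclass
class Embedding2D:
    """n×2 coordinates with the KL-divergence trace of the optimization."""

    ids: np.ndarray
    Y: np.ndarray
    kl_trace: list[tuple[int, float]] = field(default_factory=list)
    schedule: OptimizerSchedule | None = None

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    def kl_at(self, iteration: int) -> float:
        for it, kl in self.kl_trace:
            if it == iteration:
                return kl
        raise KeyError(f"iteration {iteration} was not logged")

    @property
    def final_kl(self) -> float:
        return self.kl_trace[-1][1]


def build_knn_graph(
    vectors, k: int, mode: str = "exact", metric: str | None = None
) -> np.ndarray:
    """Neighbor index lists (n×k) for a vector set or raw array."""
    if isinstance(vectors, VectorSet):
        X = vectors.X
        metric = metric or vectors.metric
    else:
        X = vectors
        metric = metric or "euclidean"
    return knn_indices(X, k, mode=mode, metric=metric)


def uniform_affinities(knn_idx: np.ndarray, k: int | None = None) -> AffinityGraph:
    """Uniform affinities on the kNN graph: w_j|i = 1/k, p_ij symmetrized.

    p_ij = (w_j|i + w_i|j) / (2n), so the matrix is symmetric, nonnegative,
    sums to exactly 1, and each row has between k and 2k nonzeros.
    """
    knn_idx = np.asarray(knn_idx)
    n, k_actual = knn_idx.shape
    k = k or k_actual
    rows = np.repeat(np.arange(n), k_actual)
    W = sp.csr_matrix(
        (np.full(n * k_actual, 1.0 / k), (rows, knn_idx.ravel())), shape=(n, n)
    )
    P = ((W + W.T) / (2.0 * n)).tocsr()
    graph = AffinityGraph(P=P, k=k)
    graph.validate()
    return graph


def _pca_init(X, seed: int = 0, scale: float = 1e-4) -> np.ndarray:
    """First two principal components, scaled so PC1 has sd ``scale``."""
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        # implicit centering via dense top-2 SVD of the centered Gram is
        # overkill at desk scale; densify
        Xc = np.asarray(X.todense()) - mean
    else:
        X = np.asarray(X, dtype=np.float64)
        Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    Y = U[:, :2] * S[:2]
    # canonical signs for determinism
    for c in range(2):
        j = np.argmax(np.abs(Y[:, c]))
        if Y[j, c] < 0:
            Y[:, c] = -Y[:, c]
    sd = Y[:, 0].std()
    if sd == 0:
        sd = 1.0
    return np.ascontiguousarray(Y * (scale / sd))


def tsne_embed(
    P: AffinityGraph,
    vectors_or_init,
    schedule: OptimizerSchedule | None = None,
    repulsion="exact",
    ids=None,
    log_every: int = 50,
) -> Embedding2D:
    """Run the modified t-SNE optimizer on an affinity graph.

    ``vectors_or_init`` is either the high-dimensional vectors (PCA
    initialization is computed from them) or an explicit n×2 starting layout.
    ``repulsion`` is "exact" or a callable ``f(Y) -> (forces, Z)`` implementing
    an approximate backend (contract: final KL within 5 % of the exact mode).
    The KL trace is logged every ``log_every`` iterations plus at the first
    post-exaggeration iteration and the last one.
    """
    schedule = schedule or OptimizerSchedule()
    P.validate(tol=1e-8)
    n = P.n
    if n < 4:
        raise ValueError("need at least 4 points")

    if repulsion == "exact":
        repulsion_fn = _kernels.repulsion_exact
    elif callable(repulsion):
        repulsion_fn = repulsion
    else:
        raise ValueError(
            "repulsion must be 'exact' or a callable backend; no approximate "
            "backend ships with this package"
        )

    if isinstance(vectors_or_init, VectorSet):
        if ids is None:
            ids = vectors_or_init.ids
        Y = _pca_init(vectors_or_init.X, seed=schedule.seed)
    else:
        arr = np.asarray(vectors_or_init, dtype=np.float64)
        if arr.shape == (n, 2):
            Y = np.ascontiguousarray(arr.copy())
        else:
            Y = _pca_init(arr, seed=schedule.seed)
    if ids is None:
        ids = np.arange(n)

    lr = schedule.learning_rate if schedule.learning_rate is not None else n / 12.0
    Pm = P.P.tocsr()
    indptr, indices, data = Pm.indptr, Pm.indices, Pm.data.astype(np.float64)

    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)
    trace: list[tuple[int, float]] = []
    log_points = {schedule.n_exaggeration + 1, schedule.n_iter}

    for t in range(schedule.n_iter):
        rho = schedule.rho(t)
        F_att = _kernels.attraction_csr(indptr, indices, data, Y)
        F_rep, Z = repulsion_fn(Y)
        grad = rho * F_att - F_rep / Z

        same_sign = np.sign(grad) == np.sign(velocity)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, 0.01, None, out=gains)
        velocity = schedule.momentum_at(t) * velocity - lr * gains * grad
        Y += velocity
        Y -= Y.mean(axis=0)

        it = t + 1
        if it % log_every == 0 or it in log_points:
            _, Z_now = repulsion_fn(Y)
            kl = _kernels.kl_csr(indptr, indices, data, Y, Z_now)
            if not trace or trace[-1][0] != it:
                trace.append((it, float(kl)))

    return Embedding2D(ids=np.asarray(ids), Y=Y, kl_trace=trace, schedule=schedule)


def align_orientation(embedding: Embedding2D, reference: Embedding2D) -> Embedding2D:
    """Flip the embedding's axes to match a reference over shared ids.

    Exhaustively evaluates the four sign pairs (±x, ±y) and keeps the one
    maximizing the sum of per-axis Pearson correlations with the reference.
    Requires at least 2 shared ids.
    """
    ref_pos = {i: p for p, i in enumerate(reference.ids.tolist())}
    shared = [(p, ref_pos[i]) for p, i in enumerate(embedding.ids.tolist())
              if i in ref_pos]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared ids to align")
    own_idx = np.array([a for a, _ in shared])
    ref_idx = np.array([b for _, b in shared])
    A = embedding.Y[own_idx]
    B = reference.Y[ref_idx]

    def corr(u, v):
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    best_score, best_pair = -np.inf, (1.0, 1.0)
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            score = corr(sx * A[:, 0], B[:, 0]) + corr(sy * A[:, 1], B[:, 1])
            if score > best_score:
                best_score, best_pair = score, (sx, sy)
    Y = embedding.Y * np.array(best_pair)
    return Embedding2D(ids=embedding.ids, Y=Y, kl_trace=list(embedding.kl_trace),
                       schedule=embedding.schedule)


def write_embedding(embedding: Embedding2D, path_prefix: str) -> None:
    """Write coordinates as TSV (id, x, y) plus a JSON sidecar with the trace."""
    import pandas as pd

    pd.DataFrame({
        "id": embedding.ids, "x": embedding.Y[:, 0], "y": embedding.Y[:, 1],
    }).to_csv(f"{path_prefix}.tsv", sep="\t", index=False)
    sched = embedding.schedule
    meta = {
        "kl_trace": [[int(i), float(v)] for i, v in embedding.kl_trace],
        "schedule": None if sched is None else {
            "n_iter": sched.n_iter, "n_exaggeration": sched.n_exaggeration,
            "rho_start": sched.rho_start, "learning_rate": sched.learning_rate,
            "momentum_exaggeration": sched.momentum_exaggeration,
            "momentum": sched.momentum, "seed": sched.seed,
        },
    }
    with open(f"{path_prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh)


def read_embedding(path_prefix: str) -> Embedding2D:
    import pandas as pd

    df = pd.read_csv(f"{path_prefix}.tsv", sep="\t", dtype={"id": str})
    with open(f"{path_prefix}.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    sched = None
    if meta.get("schedule"):
        sched = OptimizerSchedule(**meta["schedule"])
    return Embedding2D(
        ids=df["id"].to_numpy(),
        Y=df[["x", "y"]].to_numpy(dtype=np.float64),
        kl_trace=[(int(i), float(v)) for i, v in meta["kl_trace"]],
        schedule=sched,
    )
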
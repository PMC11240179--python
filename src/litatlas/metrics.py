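"""kNN-based corpus statistics for high-dimensional and 2-D representations.

All statistics are built on exact k=10 nearest neighbors by default:

- *kNN accuracy*: fraction of held-out labeled papers whose majority-neighbor
  label (among labeled training papers) matches their own, with a stratified
  random-guessing chance level;
- *year RMSE*: error of predicting publication year as the mean year of the
  k neighbors, with a chance level using k random papers instead;
- *kNN recall*: mean overlap between a paper's neighbors in the
  high-dimensional space and in the 2-D embedding;
- *isolatedness*: mean fraction of a corpus member's neighbors that belong to
  the same corpus (100 % = fully detached literature);
- *kNN overlap by year*: fraction of a source corpus's neighbors carrying a
  target discipline label, tracked per publication year;
- *region flag fractions*: counts of flagged (e.g. retracted) papers inside a
  2-D region.

Determinism: distance ties break toward the lower index and majority-vote
ties toward the nearest neighbor's label; subsampling is controlled by a seed
(explicit index arrays can be supplied instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embed import Embedding2D
from .ingest import SubcorpusMask
from .neighbors import exact_knn
from .vectorize import VectorSet

__all__ = [
    "MetricReport",
    "knn_label_accuracy",
    "chance_level_accuracy",
    "knn_year_rmse",
    "knn_recall",
    "isolatedness",
    "knn_overlap_series",
    "region_flag_fraction",
]


@dataclass
class MetricReport:
    """One named statistic with the sizes and seed that produced it."""

    name: str
    value: float  # percent for rates, years for RMSE
    k: int | None = None
    n_train: int | None = None
    n_test: int | None = None
    seed: int | None = None
    per_point: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"metric": self.name, "value": float(self.value), "k": self.k,
                "n_train": self.n_train, "n_test": self.n_test,
                "seed": self.seed, **self.extra}


def _as_array(vectors) -> np.ndarray:
    if isinstance(vectors, VectorSet):
        return vectors.dense()
    if isinstance(vectors, Embedding2D):
        return vectors.Y
    return np.asarray(vectors)


def _metric_of(vectors) -> str:
    return vectors.metric if isinstance(vectors, VectorSet) else "euclidean"


def _labeled_indices(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    return np.array([i for i, lab in enumerate(labels)
                     if lab is not None and lab == lab and lab != ""])


def _majority_vote(neighbor_labels: list) -> str:
    """Majority label; ties resolve to the nearest tied neighbor's label."""
    counts: dict = {}
    for lab in neighbor_labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in neighbor_labels:  # neighbor order = increasing distance
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def knn_label_accuracy(
    vectors, labels, k: int = 10, test_size: int = 5000, seed: int = 0,
    test_idx: np.ndarray | None = None,
) -> MetricReport:
    """Accuracy of k-nearest-neighbor majority-label prediction, in percent.

    Test points are drawn from the labeled papers; neighbors are searched
    among the remaining labeled papers. Pass ``test_idx`` (global indices)
    to fix the split explicitly.
    """
    X = _as_array(vectors)
    labels = np.asarray(labels, dtype=object)
    labeled = _labeled_indices(labels)
    if len(set(labels[labeled].tolist())) < 2:
        raise ValueError("need at least 2 distinct labels")
    if test_idx is None:
        if test_size > len(labeled) - 1:
            raise ValueError("test_size exceeds labeled count")
        rng = np.random.default_rng(seed)
        test_idx = rng.choice(labeled, size=test_size, replace=False)
    test_idx = np.asarray(test_idx)
    train_idx = np.setdiff1d(labeled, test_idx)

    nbr = exact_knn(X[train_idx], k, metric=_metric_of(vectors), queries=X[test_idx])
    correct = 0
    for row, ti in enumerate(test_idx):
        nlabs = [labels[train_idx[j]] for j in nbr[row]]
        if _majority_vote(nlabs) == labels[ti]:
            correct += 1
    acc = 100.0 * correct / len(test_idx)
    return MetricReport("knn_label_accuracy", acc, k=k, n_train=len(train_idx),
                        n_test=len(test_idx), seed=seed)


def chance_level_accuracy(
    labels, test_size: int = 10000, seed: int = 0,
    test_idx: np.ndarray | None = None,
) -> MetricReport:
    """Chance-level accuracy from stratified random guessing, in percent.

    Predictions are sampled from the empirical label distribution of the
    training papers (all labeled papers outside the test set).
    """
    labels = np.asarray(labels, dtype=object)
    labeled = _labeled_indices(labels)
    if len(labeled) == 0:
        raise ValueError("need at least 1 labeled paper")
    rng = np.random.default_rng(seed)
    if test_idx is None:
        test_size = min(test_size, len(labeled))
        test_idx = rng.choice(labeled, size=test_size, replace=False)
    test_idx = np.asarray(test_idx)
    train_idx = np.setdiff1d(labeled, test_idx)
    if len(train_idx) == 0:
        train_idx = labeled
    train_labels = labels[train_idx]
    uniq, counts = np.unique(train_labels.astype(str), return_counts=True)
    probs = counts / counts.sum()
    preds = rng.choice(uniq, size=len(test_idx), p=probs)
    acc = 100.0 * float(np.mean(preds == labels[test_idx].astype(str)))
    return MetricReport("chance_level_accuracy", acc, k=None,
                        n_train=len(train_idx), n_test=len(test_idx), seed=seed)


def knn_year_rmse(
    vectors, years, k: int = 10, test_size: int = 5000, seed: int = 0,
    mode: str = "knn", test_idx: np.ndarray | None = None,
) -> MetricReport:
    """RMSE (in years) of predicting publication year from k neighbors.

    ``knn`` predicts the mean year of the k nearest training papers;
    ``chance`` predicts the mean year of k uniformly drawn training papers.
    """
    X = _as_array(vectors)
    years = np.asarray(years, dtype=float)
    n = len(years)
    rng = np.random.default_rng(seed)
    if test_idx is None:
        if test_size > n - k:
            raise ValueError("test_size too large")
        test_idx = rng.choice(n, size=test_size, replace=False)
    test_idx = np.asarray(test_idx)
    train_idx = np.setdiff1d(np.arange(n), test_idx)

    if mode == "knn":
        nbr = exact_knn(X[train_idx], k, metric=_metric_of(vectors),
                        queries=X[test_idx])
        preds = years[train_idx][nbr].mean(axis=1)
    elif mode == "chance":
        draws = rng.integers(0, len(train_idx), size=(len(test_idx), k))
        preds = years[train_idx][draws].mean(axis=1)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    err = preds - years[test_idx]
    rmse = float(np.sqrt(np.mean(err ** 2)))
    return MetricReport(f"year_rmse_{mode}", rmse, k=k, n_train=len(train_idx),
                        n_test=len(test_idx), seed=seed, per_point=err)


def knn_recall(
    highD, lowD, k: int = 10, subset_size: int = 10000, seed: int = 0,
    subset_idx: np.ndarray | None = None,
) -> MetricReport:
    """Mean overlap (percent) between kNN sets in two representations.

    For each sampled paper, |kNN_high ∩ kNN_low| / k; neighbor sets are exact
    and searched over the full dataset. Requires identical ids in both sets.
    """
    if isinstance(highD, VectorSet) and isinstance(lowD, (VectorSet, Embedding2D)):
        low_ids = lowD.ids
        if len(highD.ids) != len(low_ids) or (np.asarray(highD.ids) != np.asarray(low_ids)).any():
            raise ValueError("high- and low-dimensional sets must share ids")
    Xh = _as_array(highD)
    Xl = _as_array(lowD)
    n = Xh.shape[0]
    rng = np.random.default_rng(seed)
    if subset_idx is None:
        subset_idx = rng.choice(n, size=min(subset_size, n), replace=False)
    subset_idx = np.asarray(subset_idx)

    nbr_h = exact_knn(Xh, k, metric=_metric_of(highD), queries=Xh[subset_idx],
                      query_self_index=subset_idx)
    nbr_l = exact_knn(Xl, k, metric=_metric_of(lowD), queries=Xl[subset_idx],
                      query_self_index=subset_idx)
    overlaps = np.array([
        len(set(nbr_h[i].tolist()) & set(nbr_l[i].tolist())) / k
        for i in range(len(subset_idx))
    ])
    return MetricReport("knn_recall", 100.0 * float(overlaps.mean()), k=k,
                        n_test=len(subset_idx), seed=seed, per_point=overlaps)


def isolatedness(
    vectors, mask, k: int = 10, subset_size: int = 5000, seed: int = 0,
    subset_idx: np.ndarray | None = None,
) -> MetricReport:
    """Mean fraction (percent) of corpus members' neighbors inside the corpus.

    Neighbors are searched over the entire dataset (query excluded). The
    subsample is capped at the corpus size.
    """
    X = _as_array(vectors)
    mask = mask.mask if isinstance(mask, SubcorpusMask) else np.asarray(mask, dtype=bool)
    members = np.flatnonzero(mask)
    if len(members) < k + 1:
        raise ValueError(f"corpus must have at least k+1={k + 1} members")
    rng = np.random.default_rng(seed)
    if subset_idx is None:
        subset_idx = rng.choice(members, size=min(subset_size, len(members)),
                                replace=False)
    subset_idx = np.asarray(subset_idx)
    nbr = exact_knn(X, k, metric=_metric_of(vectors), queries=X[subset_idx],
                    query_self_index=subset_idx)
    fractions = mask[nbr].mean(axis=1)
    return MetricReport("isolatedness", 100.0 * float(fractions.mean()), k=k,
                        n_test=len(subset_idx), seed=seed, per_point=fractions,
                        extra={"corpus_size": int(len(members))})


def knn_overlap_series(
    vectors, source_mask, target_mask, years, k: int = 10,
    per_year_cap: int = 500, seed: int = 0,
) -> pd.DataFrame:
    """Per-year mean fraction of source papers' neighbors in the target set.

    For every calendar year, up to ``per_year_cap`` source-corpus papers are
    sampled (all of them when fewer are available); each contributes the
    fraction of its k exact high-dimensional neighbors carrying the target
    label. Returns a DataFrame (year, overlap, n_sampled); smoothing is left
    to the trends module.
    """
    X = _as_array(vectors)
    src = source_mask.mask if isinstance(source_mask, SubcorpusMask) else np.asarray(source_mask, dtype=bool)
    tgt = target_mask.mask if isinstance(target_mask, SubcorpusMask) else np.asarray(target_mask, dtype=bool)
    years = np.asarray(years)
    if not src.any():
        raise ValueError("source corpus is empty")
    rng = np.random.default_rng(seed)

    sampled: list[np.ndarray] = []
    year_values = np.unique(years[src])
    for yr in year_values:
        pool = np.flatnonzero(src & (years == yr))
        take = min(per_year_cap, len(pool))
        sampled.append(rng.choice(pool, size=take, replace=False))
    all_idx = np.concatenate(sampled)
    nbr = exact_knn(X, k, metric=_metric_of(vectors), queries=X[all_idx],
                    query_self_index=all_idx)
    frac = tgt[nbr].mean(axis=1)

    rows, pos = [], 0
    for yr, idx in zip(year_values, sampled):
        m = len(idx)
        rows.append({"year": int(yr), "overlap": float(frac[pos:pos + m].mean()),
                     "n_sampled": m})
        pos += m
    return pd.DataFrame(rows)


def region_flag_fraction(embedding, flags, region) -> tuple[int, int, float]:
    """Count flagged papers inside a 2-D region (boundary inclusive).

    ``region`` is an axis-aligned box (xmin, xmax, ymin, ymax) or a polygon
    given as an (m, 2) vertex array. Returns (count_flagged, count_total,
    fraction); raises when no point falls inside the region.
    """
    Y = embedding.Y if isinstance(embedding, Embedding2D) else np.asarray(embedding)
    flags = np.asarray(flags, dtype=bool)
    region_arr = np.asarray(region, dtype=float)
    if region_arr.shape == (4,):
        xmin, xmax, ymin, ymax = region_arr
        inside = ((Y[:, 0] >= xmin) & (Y[:, 0] <= xmax)
                  & (Y[:, 1] >= ymin) & (Y[:, 1] <= ymax))
    elif region_arr.ndim == 2 and region_arr.shape[1] == 2:
        from shapely.geometry import Point, Polygon

        poly = Polygon(region_arr)
        inside = np.array([poly.covers(Point(x, y)) for x, y in Y])
    else:
        raise ValueError("region must be (xmin, xmax, ymin, ymax) or an (m,2) polygon")
    total = int(inside.sum())
    if total == 0:
        raise ValueError("region contains no points")
    flagged = int((inside & flags).sum())
    return flagged, total, flagged / total
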
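"""Independent brute-force oracles used to check the package's kNN statistics.

Everything here is written as plain Python loops over explicit distance
computations, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math
import re
from collections import Counter

import numpy as np


def naive_knn(X, k, query_rows=None, exclude=None):
    """k nearest neighbors by exhaustive sort of (distance, index) pairs.

    ``query_rows`` defaults to all rows of X (self excluded); ``exclude``
    optionally gives, per query, one index to skip (the query's own row).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if query_rows is None:
        Q = X
        exclude = list(range(n))
    else:
        Q = np.asarray(query_rows, dtype=float)
        if exclude is None:
            exclude = [None] * len(Q)
    out = []
    for qi, q in enumerate(Q):
        pairs = []
        for j in range(n):
            if exclude[qi] == j:
                continue
            dist = math.dist(q, X[j])
            pairs.append((dist, j))
        pairs.sort()
        out.append([j for _, j in pairs[:k]])
    return np.array(out)


def naive_majority(neighbor_labels):
    """Majority label with ties resolved toward the nearest tied neighbor."""
    counts = Counter(neighbor_labels)
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in neighbor_labels:
        if lab in tied:
            return lab


def naive_accuracy(X, labels, test_idx, k):
    labels = np.asarray(labels, dtype=object)
    labeled = [i for i, lab in enumerate(labels) if lab not in (None, "")]
    train = sorted(set(labeled) - set(int(i) for i in test_idx))
    Xtr = np.asarray(X, dtype=float)[train]
    hits = 0
    for ti in test_idx:
        nbr = naive_knn(Xtr, k, query_rows=[np.asarray(X, dtype=float)[ti]])[0]
        if naive_majority([labels[train[j]] for j in nbr]) == labels[ti]:
            hits += 1
    return 100.0 * hits / len(test_idx)


def naive_year_rmse(X, years, test_idx, k):
    X = np.asarray(X, dtype=float)
    years = np.asarray(years, dtype=float)
    train = sorted(set(range(len(X))) - set(int(i) for i in test_idx))
    sq = 0.0
    for ti in test_idx:
        nbr = naive_knn(X[train], k, query_rows=[X[ti]])[0]
        pred = sum(years[train[j]] for j in nbr) / k
        sq += (pred - years[ti]) ** 2
    return math.sqrt(sq / len(test_idx))


def naive_recall(Xh, Xl, subset_idx, k):
    Xh = np.asarray(Xh, dtype=float)
    Xl = np.asarray(Xl, dtype=float)
    total = 0.0
    for i in subset_idx:
        nh = set(naive_knn(Xh, k, query_rows=[Xh[i]], exclude=[int(i)])[0].tolist())
        nl = set(naive_knn(Xl, k, query_rows=[Xl[i]], exclude=[int(i)])[0].tolist())
        total += len(nh & nl) / k
    return 100.0 * total / len(subset_idx)


def naive_isolatedness(X, mask, subset_idx, k):
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    total = 0.0
    for i in subset_idx:
        nbr = naive_knn(X, k, query_rows=[X[i]], exclude=[int(i)])[0]
        total += sum(1 for j in nbr if mask[j]) / k
    return 100.0 * total / len(subset_idx)


def naive_token_counts(texts):
    """Exhaustive token enumeration: lowercase runs of >=2 word characters."""
    counts = []
    vocab = set()
    for text in texts:
        toks = re.findall(r"\w\w+", text.lower())
        c = Counter(toks)
        counts.append(c)
        vocab.update(c)
    return sorted(vocab), counts


def naive_tfidf_entry(c_ij, n_docs, df_j):
    """The log-scaled TF-IDF weight of a single positive count."""
    return (1.0 + math.log(c_ij)) * (1.0 + math.log((1.0 + n_docs) / (1.0 + df_j)))


def naive_align_signs(A, B):
    """Best (±x, ±y) pair by exhaustive enumeration with scipy's pearsonr."""
    from scipy.stats import pearsonr

    best, best_pair = -np.inf, None
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            score = (pearsonr(sx * A[:, 0], B[:, 0]).statistic
                     + pearsonr(sy * A[:, 1], B[:, 1]).statistic)
            if score > best:
                best, best_pair = score, (sx, sy)
    return best_pair
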
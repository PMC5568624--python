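"""Filter feature-ranking methods.

Seven rankers map a (standardized) feature table to a full ordering of
its columns: ReliefF, Fisher score, Chi-square, information gain,
conditional mutual information maximization (CMIM), and minimum
redundancy / maximum relevance in its difference (MID) and quotient
(MIQ) variants.

Information-theoretic rankers operate on equal-width discretized
features (10 bins by default); mutual information uses the plug-in
estimator with natural logarithms. All rankers are deterministic; ties
are broken by ascending feature index everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .types import FeatureTable, RankedList

DEFAULT_N_BINS = 10
_EPS = 1e-12


def _order_desc(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score, ties by ascending index."""
    k = scores.size
    return np.lexsort((np.arange(k), -scores))


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, int]:
    classes, enc = np.unique(y, return_inverse=True)
    return enc, classes.size


# ---------------------------------------------------------------------------
# discretization and mutual information


def discretize(column: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-width discretization into integer labels 0..n_bins-1.

    Bin edges span [min, max]; the top bin is right-closed. A constant
    column maps to all zeros.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    column = np.asarray(column, dtype=float)
    lo, hi = column.min(), column.max()
    if lo == hi:
        return np.zeros(column.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    labels = np.searchsorted(edges, column, side="right") - 1
    return np.clip(labels, 0, n_bins - 1)


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    return np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two discrete label sequences (nats)."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    joint = _contingency(a, b) / a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])))


def conditional_mutual_information(a: np.ndarray, b: np.ndarray,
                                   c: np.ndarray) -> float:
    """I(a; b | c) = sum_c p(c) I(a; b | C = c), plug-in estimate."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    c = np.asarray(c, dtype=int)
    n = a.size
    total = 0.0
    for val in np.unique(c):
        mask = c == val
        total += mask.sum() / n * mutual_information(a[mask], b[mask])
    return total


# ---------------------------------------------------------------------------
# rankers


def fisher_rank(X: FeatureTable) -> RankedList:
    """Fisher score: between-class scatter over within-class scatter."""
    y, n_classes = _encode_labels(X.labels)
    if n_classes < 2:
        raise ValueError("Fisher score requires at least 2 classes")
    v = X.values
    mu = v.mean(axis=0)
    num = np.zeros(X.n_features)
    den = np.zeros(X.n_features)
    for c in range(n_classes):
        vc = v[y == c]
        nc = vc.shape[0]
        num += nc * (vc.mean(axis=0) - mu) ** 2
        den += nc * vc.var(axis=0)
    scores = num / (den + _EPS)
    return RankedList(_order_desc(scores), scores, "Fisher", list(X.feature_names))


def chi2_rank(X: FeatureTable, n_bins: int = DEFAULT_N_BINS) -> RankedList:
    """Pearson chi-square statistic of the bin x class contingency table."""
    y, _ = _encode_labels(X.labels)
    scores = np.empty(X.n_features)
    for j in range(X.n_features):
        obs = _contingency(discretize(X.values[:, j], n_bins), y)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        mask = expected > 0
        scores[j] = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    return RankedList(_order_desc(scores), scores, "Chi2", list(X.feature_names))


def infogain_rank(X: FeatureTable, n_bins: int = DEFAULT_N_BINS) -> RankedList:
    """Information gain H(Y) - H(Y | binned feature) = I(bin; Y)."""
    y, _ = _encode_labels(X.labels)
    scores = np.array([
        mutual_information(discretize(X.values[:, j], n_bins), y)
        for j in range(X.n_features)
    ])
    return RankedList(_order_desc(scores), scores, "IG", list(X.feature_names))


def relieff_rank(X: FeatureTable, k: int = 10) -> RankedList:
    """Multi-class ReliefF with all instances as update anchors.

    Nearest hits/misses by Manhattan distance; per-feature contributions
    normalized by the feature's value range; miss contributions weighted
    by class priors renormalized over non-target classes.
    """
    y, n_classes = _encode_labels(X.labels)
    v = X.values
    n, p = v.shape
    counts = np.bincount(y, minlength=n_classes)
    if np.any(counts <= k):
        small = counts.min()
        raise ValueError(
            f"a class has only {small} members; ReliefF with k={k} needs "
            f"more than k per class - use a smaller k"
        )
    priors = counts / n
    span = v.max(axis=0) - v.min(axis=0)
    span[span == 0] = 1.0
    w = np.zeros(p)
    dist = cdist(v, v, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    for i in range(n):
        ci = y[i]
        same = np.where(y == ci)[0]
        hits = same[np.argsort(dist[i, same], kind="stable")[:k]]
        w -= np.sum(np.abs(v[hits] - v[i]) / span, axis=0) / (n * k)
        for c in range(n_classes):
            if c == ci:
                continue
            other = np.where(y == c)[0]
            misses = other[np.argsort(dist[i, other], kind="stable")[:k]]
            weight = priors[c] / (1.0 - priors[ci])
            w += weight * np.sum(np.abs(v[misses] - v[i]) / span, axis=0) / (n * k)
    return RankedList(_order_desc(w), w, "ReliefF", list(X.feature_names))


def cmim_rank(X: FeatureTable, n_bins: int = DEFAULT_N_BINS) -> RankedList:
    """Conditional mutual information maximization (greedy, full ordering).

    First picks the feature with maximal I(f; Y); each subsequent pick
    maximizes min over already-selected g of I(f; Y | g). The reported
    score of a feature is its criterion value at selection time.
    """
    y, _ = _encode_labels(X.labels)
    cols = [discretize(X.values[:, j], n_bins) for j in range(X.n_features)]
    p = X.n_features
    rel = np.array([mutual_information(cols[j], y) for j in range(p)])
    partial = np.full(p, np.inf)  # running min of conditional MIs
    selected: list[int] = []
    scores = np.zeros(p)
    remaining = list(range(p))
    while remaining:
        crit = rel if not selected else partial
        best = min(remaining, key=lambda j: (-crit[j], j))
        scores[best] = crit[best]
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            cmi = conditional_mutual_information(cols[j], y, cols[best])
            if cmi < partial[j]:
                partial[j] = cmi
    return RankedList(np.array(selected), scores, "CMIM", list(X.feature_names))


def mrmr_rank(X: FeatureTable, variant: str = "MID",
              n_bins: int = DEFAULT_N_BINS) -> RankedList:
    """Minimum redundancy / maximum relevance (greedy, full ordering).

    Relevance D = I(f; Y); redundancy R = mean I(f; g) over selected g.
    variant "MID" maximizes D - R, "MIQ" maximizes D / R (zero R guarded
    by a 1e-12 floor). The first pick maximizes relevance for both.
    """
    if variant not in ("MID", "MIQ"):
        raise ValueError("variant must be 'MID' or 'MIQ'")
    y, _ = _encode_labels(X.labels)
    cols = [discretize(X.values[:, j], n_bins) for j in range(X.n_features)]
    p = X.n_features
    rel = np.array([mutual_information(cols[j], y) for j in range(p)])
    mi_sum = np.zeros(p)
    selected: list[int] = []
    scores = np.zeros(p)
    remaining = list(range(p))
    while remaining:
        if not selected:
            crit = rel.copy()
        else:
            redundancy = mi_sum / len(selected)
            if variant == "MID":
                crit = rel - redundancy
            else:
                crit = rel / np.maximum(redundancy, _EPS)
        best = min(remaining, key=lambda j: (-crit[j], j))
        scores[best] = crit[best]
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            mi_sum[j] += mutual_information(cols[j], cols[best])
    return RankedList(
        np.array(selected), scores, f"MRMR-{variant}", list(X.feature_names)
    )


# ---------------------------------------------------------------------------
# ranker registry


@dataclass(frozen=True)
class Ranker:
    """A named, deterministic table -> RankedList callable."""

    name: str
    fn: Callable[..., RankedList]
    kwargs: dict = field(default_factory=dict)

    def __call__(self, table: FeatureTable) -> RankedList:
        lst = self.fn(table, **self.kwargs)
        lst.method = self.name
        return lst


def default_rankers(relieff_k: int = 10,
                    n_bins: int = DEFAULT_N_BINS) -> dict[str, Ranker]:
    """The seven filter rankers with their default settings."""
    return {
        "ReliefF": Ranker("ReliefF", relieff_rank, {"k": relieff_k}),
        "Fisher": Ranker("Fisher", fisher_rank),
        "Chi2": Ranker("Chi2", chi2_rank, {"n_bins": n_bins}),
        "IG": Ranker("IG", infogain_rank, {"n_bins": n_bins}),
        "CMIM": Ranker("CMIM", cmim_rank, {"n_bins": n_bins}),
        "MRMR-MID": Ranker("MRMR-MID", mrmr_rank, {"variant": "MID", "n_bins": n_bins}),
        "MRMR-MIQ": Ranker("MRMR-MIQ", mrmr_rank, {"variant": "MIQ", "n_bins": n_bins}),
    }
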
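"""Evaluation protocol: stability, similarity, accuracy, knee selection.

Stability of a ranker is the mean pairwise Tanimoto overlap of the
top-d feature sets it produces on bootstrap replicates of the training
table. Similarity applies the same overlap to the top-d sets of two
different methods on the full table. Accuracy is scored by repeated
random sub-sampling validation (stratified splits) with a 1-NN and an
LM-trained feed-forward net; the knee of each accuracy curve is chosen
by the Kneedle criterion.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .features import standardize
from .mlfn import ConvergenceError, MLFNClassifier
from .types import (STAGES, AccuracyCurve, FeatureTable, RankedList,
                    StabilityProfile)

logger = logging.getLogger(__name__)

DEFAULT_STABILITY_D = tuple(range(1, 30, 2))  # d = 1, 3, ..., 29
DEFAULT_ACCURACY_D = tuple(range(1, 16, 2))  # d = 1, 3, ..., 15


# ---------------------------------------------------------------------------
# set overlap


def tanimoto(s: Iterable[int], s2: Iterable[int]) -> float:
    """Tanimoto overlap |s & s2| / |s | s2| of two feature sets.

    Two empty sets are identical (1); one empty set shares nothing (0).
    """
    a, b = set(s), set(s2)
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


# ---------------------------------------------------------------------------
# stability and similarity


def bootstrap_rankings(
    ranker: Callable[[FeatureTable], RankedList],
    X: FeatureTable,
    n_boot: int = 50,
    seed: int = 0,
    restandardize: bool = True,
) -> list[RankedList]:
    """Rankings of ``n_boot`` bootstrap replicates of the table rows.

    Each replicate resamples the n rows with replacement and is
    re-standardized before ranking (so scale conventions hold within
    every replicate).
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    out = []
    n = X.n_epochs
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = X.subset_rows(idx)
        if restandardize:
            rep = standardize(rep)
        out.append(ranker(rep))
    return out


def stability_from_rankings(rankings: Sequence[RankedList],
                            d_values: Sequence[int]) -> np.ndarray:
    """Mean pairwise Tanimoto of top-d sets, per d."""
    n_feat = rankings[0].n_features
    stab = np.empty(len(d_values))
    for di, d in enumerate(d_values):
        if d > n_feat:
            raise ValueError(f"d={d} exceeds feature count {n_feat}")
        tops = [r.top(d) for r in rankings]
        vals = [
            tanimoto(tops[i], tops[j])
            for i in range(len(tops))
            for j in range(i + 1, len(tops))
        ]
        stab[di] = float(np.mean(vals))
    return stab


def stability_profile(
    ranker: Callable[[FeatureTable], RankedList],
    X: FeatureTable,
    n_boot: int = 50,
    d_values: Sequence[int] = DEFAULT_STABILITY_D,
    seed: int = 0,
    method: str | None = None,
) -> StabilityProfile:
    """Bootstrap stability of one ranking method over subset sizes d."""
    rankings = bootstrap_rankings(ranker, X, n_boot, seed)
    name = method or getattr(ranker, "name", rankings[0].method)
    return StabilityProfile(
        method=name,
        d_values=np.asarray(d_values, dtype=int),
        stability=stability_from_rankings(rankings, d_values),
    )


def similarity_matrix(lists: Sequence[RankedList], d: int = 29) -> np.ndarray:
    """Symmetric matrix of pairwise top-d Tanimoto overlaps."""
    m = len(lists)
    tops = [r.top(d) for r in lists]
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = tanimoto(tops[i], tops[j])
    return sim


# ---------------------------------------------------------------------------
# balanced per-subject epoch sampling


def _largest_remainder(quota: int, counts: np.ndarray) -> np.ndarray:
    """Allocate ``quota`` over categories proportionally to ``counts``.

    Largest-remainder rounding, ties broken by ascending category index;
    allocations never exceed the available counts.
    """
    total = counts.sum()
    exact = quota * counts / total
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    # distribute leftovers by descending remainder, index tie-break
    order = np.lexsort((np.arange(counts.size), -remainder))
    leftover = quota - alloc.sum()
    for idx in order:
        if leftover == 0:
            break
        if alloc[idx] < counts[idx]:
            alloc[idx] += 1
            leftover -= 1
    # cap pathological over-allocation (only possible at quota == total)
    over = alloc - counts
    if np.any(over > 0):
        alloc = np.minimum(alloc, counts)
        for idx in order:
            while alloc.sum() < quota and alloc[idx] < counts[idx]:
                alloc[idx] += 1
    return alloc


def balanced_subject_sampling(
    tables: Sequence[FeatureTable],
    quota: int,
    seed: int = 0,
) -> FeatureTable:
    """Draw the same number of epochs from every subject.

    Within a subject, per-stage counts are proportional to that
    subject's stage frequencies (largest-remainder rounding over the
    canonical stage order); sampling is without replacement and seeded.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for t in tables:
        subject = t.subject_ids[0] if t.n_epochs else "?"
        if quota > t.n_epochs:
            raise ValueError(
                f"quota {quota} exceeds subject {subject}'s {t.n_epochs} epochs"
            )
        stages_present = [s for s in STAGES if s in set(t.labels)]
        extra = [s for s in sorted(set(t.labels)) if s not in stages_present]
        cats = stages_present + extra
        counts = np.array([int(np.sum(t.labels == s)) for s in cats])
        alloc = _largest_remainder(quota, counts)
        chosen: list[int] = []
        for s, a in zip(cats, alloc):
            idx = np.where(t.labels == s)[0]
            chosen.extend(rng.choice(idx, size=a, replace=False).tolist())
        parts.append(t.subset_rows(sorted(chosen)))
    return FeatureTable(
        values=np.vstack([p.values for p in parts]),
        feature_names=list(tables[0].feature_names),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
    )


# ---------------------------------------------------------------------------
# classification accuracy


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of correct detections."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.size != labels.size:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    return float(np.mean(predictions == labels))


def _subsampling_runs(
    X: FeatureTable,
    order: RankedList,
    d: int,
    n_runs: int,
    train_frac: float,
    seed: int,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray],
    max_retries: int = 5,
) -> float:
    """Mean accuracy over repeated stratified random sub-sampling runs."""
    if d < 1:
        raise ValueError("d must be >= 1")
    feats = X.values[:, order.order[:d]]
    y = np.asarray(X.labels)
    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(
        n_runs * (max_retries + 1))]
    accs = []
    si = 0
    for _ in range(n_runs):
        for attempt in range(max_retries + 1):
            rs = run_seeds[si]
            si += 1
            xtr, xte, ytr, yte = train_test_split(
                feats, y, train_size=train_frac, stratify=y, random_state=rs
            )
            if not set(yte) <= set(ytr):
                logger.info("test class absent from training; run re-drawn")
                continue
            try:
                pred = fit_predict(xtr, ytr, xte, rs)
            except ConvergenceError:
                logger.info("non-convergent run re-drawn (attempt %d)", attempt)
                continue
            accs.append(accuracy(pred, yte))
            break
        else:
            raise RuntimeError("run retry cap exhausted")
    return float(np.mean(accs))


def knn_accuracy(
    X: FeatureTable,
    order: RankedList,
    d: int,
    n_runs: int = 200,
    train_frac: float = 0.7,
    seed: int = 0,
) -> float:
    """Mean 1-NN (Euclidean) accuracy on the top-d features."""

    def fit_predict(xtr, ytr, xte, rs):
        clf = KNeighborsClassifier(n_neighbors=1, metric="euclidean")
        clf.fit(xtr, ytr)
        return clf.predict(xte)

    return _subsampling_runs(X, order, d, n_runs, train_frac, seed, fit_predict)


def mlfn_accuracy(
    X: FeatureTable,
    order: RankedList,
    d: int,
    n_runs: int = 200,
    train_frac: float = 0.7,
    seed: int = 0,
    n_hidden: int = 12,
    max_iter: int = 30,
) -> float:
    """Mean accuracy of the LM-trained feed-forward net on top-d features."""

    def fit_predict(xtr, ytr, xte, rs):
        clf = MLFNClassifier(n_hidden=n_hidden, max_iter=max_iter, seed=rs)
        clf.fit(xtr, ytr)
        return clf.predict(xte)

    return _subsampling_runs(X, order, d, n_runs, train_frac, seed, fit_predict)


# ---------------------------------------------------------------------------
# knee-point selection


def kneedle(
    d_values: Sequence[int],
    accuracies: Sequence[float],
    sensitivity: float = 1.0,
) -> int:
    """Knee of a concave increasing accuracy curve (Kneedle criterion).

    Both axes are min-max normalized; the difference curve y_n - x_n is
    scanned for local maxima, a knee being declared when the curve drops
    below a local maximum's sensitivity threshold before the next local
    maximum. Several knees -> the smallest d. No knee -> the d
    maximizing the difference curve, with a warning.
    """
    x = np.asarray(d_values, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("d_values must be strictly increasing")
    xr = x.max() - x.min()
    yr = y.max() - y.min()
    xn = (x - x.min()) / xr
    yn = (y - y.min()) / yr if yr > 0 else np.zeros_like(y)
    diff = yn - xn
    lmx = [
        i for i in range(1, x.size - 1)
        if diff[i] > diff[i - 1] and diff[i] >= diff[i + 1]
    ]
    step = sensitivity * float(np.mean(np.diff(xn)))
    knees = []
    for pos, i in enumerate(lmx):
        thresh = diff[i] - step
        nxt = lmx[pos + 1] if pos + 1 < len(lmx) else x.size
        for j in range(i + 1, nxt):
            if diff[j] < thresh:
                knees.append(int(x[i]))
                break
    if knees:
        return min(knees)
    warnings.warn("no knee found; returning the difference-curve maximum",
                  RuntimeWarning, stacklevel=2)
    return int(x[int(np.argmax(diff))])


def accuracy_curve(
    X: FeatureTable,
    order: RankedList,
    classifier: str = "knn",
    d_values: Sequence[int] = DEFAULT_ACCURACY_D,
    n_runs: int = 200,
    train_frac: float = 0.7,
    seed: int = 0,
    mlfn_kwargs: dict | None = None,
) -> AccuracyCurve:
    """Accuracy as a function of d, with the Kneedle-selected optimum."""
    fn = knn_accuracy if classifier == "knn" else mlfn_accuracy
    kwargs = dict(mlfn_kwargs or {}) if classifier == "mlfn" else {}
    accs = np.array([
        fn(X, order, d, n_runs=n_runs, train_frac=train_frac, seed=seed, **kwargs)
        for d in d_values
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        opt = kneedle(d_values, accs)
    return AccuracyCurve(
        method=order.method,
        classifier=classifier,
        d_values=np.asarray(d_values, dtype=int),
        accuracy=accs,
        optimum_d=opt,
    )
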
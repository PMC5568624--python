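"""Rank aggregation: Borda count and robust rank aggregation (RRA).

Borda awards each feature N - position + 1 points per input ranking
(position 1 = best) and orders by descending total, which is
order-equivalent to the ascending sum of raw ranks.

RRA compares each feature's normalized rank vector against the order
statistics of uniformly random rankings: for the ascending normalized
ranks r_(1) <= ... <= r_(m) over m methods, rho = min_k P(Beta(k,
m-k+1) <= r_(k)), and the reported significance score is the
Bonferroni-corrected min(1, rho * m). Features are ordered by ascending
rho (the uncorrected minimum), so the ordering is not coarsened by the
clipping of the corrected score.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import beta as beta_dist

from .types import RankedList


def _check_rankings(rankings: list[RankedList]) -> int:
    if not rankings:
        raise ValueError("need at least one ranking")
    n = rankings[0].n_features
    names = rankings[0].feature_names
    for r in rankings[1:]:
        if r.n_features != n or (
            names is not None and r.feature_names is not None
            and list(r.feature_names) != list(names)
        ):
            raise ValueError("rankings cover mismatched feature sets")
    return n


def _positions(rankings: list[RankedList]) -> np.ndarray:
    """(n_features, n_methods) matrix of 1-based rank positions."""
    n = rankings[0].n_features
    pos = np.empty((n, len(rankings)), dtype=float)
    for j, r in enumerate(rankings):
        pos[r.order, j] = np.arange(1, n + 1)
    return pos


def borda(rankings: list[RankedList]) -> RankedList:
    """Borda count aggregation of one or more rankings."""
    n = _check_rankings(rankings)
    pos = _positions(rankings)
    points = (n - pos + 1).sum(axis=1)
    order = np.lexsort((np.arange(n), -points))
    return RankedList(order, points, "Borda", rankings[0].feature_names)


def rra(rankings: list[RankedList]) -> RankedList:
    """Robust rank aggregation with exact beta order-statistic p-values."""
    n = _check_rankings(rankings)
    m = len(rankings)
    if m < 2:
        raise ValueError("RRA needs at least 2 rankings")
    pos = _positions(rankings)
    r_norm = np.sort(pos / n, axis=1)  # ascending normalized ranks
    k = np.arange(1, m + 1)
    # beta CDF per feature and order statistic
    rho = beta_dist.cdf(r_norm, k[None, :], (m - k + 1)[None, :]).min(axis=1)
    scores = np.minimum(1.0, rho * m)
    order = np.lexsort((np.arange(n), rho))
    return RankedList(order, scores, "RRA", rankings[0].feature_names)
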
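"""Feature ranking: RReliefF (regression Relief) and mRMR.

Both rankers operate on the epoch-level training matrix of one
cross-validation fold; they must never see validation or test rows
(leakage contract enforced by the evaluation module).

RReliefF follows the Robnik-Sikonja & Kononenko accumulator scheme with
a full pass over instances (no subsampling, deterministic), k = 10
nearest neighbours under Manhattan distance on min-max-scaled features.

mRMR is greedy forward selection with relevance = |Pearson r(f, y)| and
redundancy = mean |Pearson r(f, selected)| (difference criterion); the
first pick is the relevance argmax.  Ties break by canonical feature
name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["RankedFeatures", "relieff_rank", "mrmr_rank", "candidate_sets"]


@dataclass(frozen=True)
class RankedFeatures:
    names: Tuple[str, ...]    # best first; a permutation of the candidates
    scores: Tuple[float, ...]
    method: str               # "relieff" | "mrmr"

    def top(self, m: int) -> Tuple[str, ...]:
        return self.names[:m]


def _order(names: Sequence[str], scores: np.ndarray) -> Tuple[Tuple[str, ...], Tuple[float, ...]]:
    # descending score, ties by canonical (alphabetical) name
    idx = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return tuple(names[i] for i in idx), tuple(float(scores[i]) for i in idx)


def relieff_rank(
    X: np.ndarray, y: np.ndarray, feature_names: Sequence[str], k: int = 10
) -> RankedFeatures:
    """RReliefF weights; higher = more relevant to the continuous target."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if k >= n:
        raise ValueError(f"k={k} neighbours require more than k instances (n={n})")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("missing or non-finite values in ranking input")
    # min-max scale features; constant features get zero diffs hence weight 0
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    y_span = y.max() - y.min()
    dy_all = np.abs(y[:, None] - y[None, :]) / (y_span if y_span > 0 else 1.0)

    dist = cdist(Xs, Xs, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    N_dC = 0.0
    N_dA = np.zeros(m)
    N_dCdA = np.zeros(m)
    w_neighbor = 1.0 / k
    for i in range(n):
        neigh = np.argpartition(dist[i], k)[:k]
        neigh = neigh[np.argsort(dist[i][neigh], kind="stable")]
        dy = dy_all[i, neigh] * w_neighbor
        dA = np.abs(Xs[neigh] - Xs[i]) * w_neighbor
        N_dC += dy.sum()
        N_dA += dA.sum(axis=0)
        N_dCdA += (dA * dy[:, None] * k).sum(axis=0)
    total = float(n)
    if N_dC <= 0 or total - N_dC <= 0:
        weights = np.zeros(m)
    else:
        weights = N_dCdA / N_dC - (N_dA - N_dCdA) / (total - N_dC)
    names, scores = _order(list(feature_names), weights)
    return RankedFeatures(names=names, scores=scores, method="relieff")


def mrmr_rank(
    X: np.ndarray, y: np.ndarray, feature_names: Sequence[str]
) -> RankedFeatures:
    """Greedy mRMR ranking of all candidate features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m < 1:
        raise ValueError("no candidate features")
    names = list(feature_names)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} zero-variance features ranked last",
            stacklevel=2,
        )
    # |corr| of every feature with y and with every other feature; the
    # zero-variance convention (correlation 0) keeps degenerate columns
    # at the bottom of the ranking
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(np.column_stack([X, y]), rowvar=False)
    full = np.nan_to_num(np.abs(full), nan=0.0)
    relevance = full[:-1, -1]
    C = full[:-1, :-1]
    selected: List[int] = []
    remaining = list(range(m))
    red_sum = np.zeros(m)
    scores = np.zeros(m)
    order: List[int] = []
    while remaining:
        if not selected:
            crit = relevance.copy()
        else:
            crit = relevance - red_sum / len(selected)
        best = min(remaining, key=lambda j: (-crit[j], names[j]))
        order.append(best)
        scores[best] = crit[best]
        remaining.remove(best)
        selected.append(best)
        red_sum += C[best]
    ranked_names = tuple(names[j] for j in order)
    ranked_scores = tuple(float(scores[j]) for j in order)
    return RankedFeatures(names=ranked_names, scores=ranked_scores, method="mrmr")


def candidate_sets(ranked: RankedFeatures | Sequence[str], top_m: int = 4) -> List[Tuple[str, ...]]:
    """All 2^m - 1 non-empty subsets of the top-m features, in a
    deterministic order (by size, then by rank positions)."""
    names = ranked.names if isinstance(ranked, RankedFeatures) else tuple(ranked)
    if len(names) < top_m:
        raise ValueError(f"ranking has {len(names)} features, need >= {top_m}")
    top = names[:top_m]
    subsets: List[Tuple[str, ...]] = []
    for size in range(1, top_m + 1):
        for combo in combinations(range(top_m), size):
            subsets.append(tuple(top[i] for i in combo))
    return subsets


def positional_subsets(top_m: int = 4) -> List[Tuple[int, ...]]:
    """Index subsets of the top-m ranks (used as grid coordinates so the
    same grid point maps onto each fold's own ranking)."""
    out: List[Tuple[int, ...]] = []
    for size in range(1, top_m + 1):
        out.extend(combinations(range(top_m), size))
    return out
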
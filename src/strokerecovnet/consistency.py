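"""Domain- and cluster-consistency of selected features across models.

Two trained models (CV reports) are compared at two granularities:

- *domain consistency*: 1 - sum_d w_d |fA_d - fB_d| / sum_d w_d over the
  four feature domains, where f*_d are per-domain selection frequencies
  and the weights w_d are the mean domain frequency across all compared
  datasets;
- *cluster consistency*: Jaccard similarity of the sets of data-driven
  feature clusters (complete-linkage hierarchical clustering of
  1 - |Spearman rho|, cut at 0.7) touched by each model's selections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "FeatureClusters",
    "domain_consistency",
    "cluster_features",
    "cluster_consistency",
]

CLUSTER_CUTOFF = 0.7  # distance cut: features merge while |rho| >= 0.3


@dataclass
class FeatureClusters:
    assignments: Dict[str, int]   # feature name -> cluster id

    def clusters_of(self, features: Iterable[str]) -> set:
        return {self.assignments[f] for f in features}


def domain_consistency(
    freq_a: Mapping[str, float],
    freq_b: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted similarity of two domain-selection-frequency profiles,
    bounded in [0, 1]; identical profiles give 1.  Weights default to the
    mean of the two profiles (the mean across all compared datasets when
    more than two are involved)."""
    domains = sorted(freq_a)
    if sorted(freq_b) != domains:
        raise ValueError("domain sets differ between the two profiles")
    if weights is None:
        weights = {d: 0.5 * (freq_a[d] + freq_b[d]) for d in domains}
    w = np.array([weights[d] for d in domains], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all-zero domain weights")
    fa = np.array([freq_a[d] for d in domains], dtype=float)
    fb = np.array([freq_b[d] for d in domains], dtype=float)
    return float(1.0 - np.sum(w * np.abs(fa - fb)) / np.sum(w))


def cluster_features(feature_matrix: pd.DataFrame) -> FeatureClusters:
    """Complete-linkage hierarchical clustering of features on the
    distance 1 - |Spearman rho|, flattened at height 0.7.

    Constant features (undefined rank correlation) are placed at maximal
    distance from everything, i.e. become singleton clusters."""
    names = list(feature_matrix.columns)
    X = feature_matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two features to cluster")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} constant features assigned singleton clusters",
            stacklevel=2,
        )
    D = 1.0 - np.abs(rho)
    D[np.isnan(D)] = 1.0
    D[const, :] = 1.0
    D[:, const] = 1.0
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    Z = linkage(squareform(D, checks=False), method="complete")
    flat = fcluster(Z, t=CLUSTER_CUTOFF, criterion="distance")
    return FeatureClusters(assignments=dict(zip(names, flat.tolist())))


def cluster_consistency(
    clusters_ref: FeatureClusters,
    selected_a: Sequence[str],
    selected_b: Sequence[str],
) -> float:
    """Jaccard similarity between the sets of reference clusters with a
    non-zero selection frequency in each model."""
    if not selected_a and not selected_b:
        raise ValueError("both selections are empty")
    ca = clusters_ref.clusters_of(selected_a)
    cb = clusters_ref.clusters_of(selected_b)
    union = ca | cb
    return float(len(ca & cb) / len(union))
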
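"""Imaginary-coherency connectivity among ROIs and the 80 network features.

The six lateralized ROIs (FR, FL, CR, CL, OR, OL) form the nodes of a
weighted graph per frequency band.  Edge weights are the band-mean
absolute imaginary part of the coherency spectrum — insensitive to
zero-lag (volume-conducted) coupling.  Graphs are sparsified with a
proportional threshold (highest percentile keeping the graph connected)
before metric extraction.

Conventions follow the Brain Connectivity Toolbox: shortest-path
distance = 1/weight, Onnela geometric-mean weighted clustering, local
efficiency as mean inverse distance inside the neighbor-induced
subgraph.

Per band: 6 global metrics (mean degree, mean strength, characteristic
path length L_w, mean clustering C_w, small-world omega, rich club) and
5 nodal metrics x 2 motor nodes (CR = affected central, CL = unaffected
central), i.e. 16 x 5 bands = 80 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import signal as sps

from .core import BAND_ORDER, Epoch, ROILayout
from .spectral import WELCH_SEGMENT_S, FeatureError, band_mask

__all__ = [
    "NODE_ORDER",
    "PrunedGraph",
    "roi_signals",
    "imag_coherency",
    "prune_graph",
    "graph_metrics",
    "nodal_metrics",
    "connectivity_block",
    "CONNECTIVITY_FEATURE_NAMES",
]

NODE_ORDER: Tuple[str, ...] = ("FR", "FL", "CR", "CL", "OR", "OL")
_AH_NODE = NODE_ORDER.index("CR")  # affected motor ROI (right = affected)
_UH_NODE = NODE_ORDER.index("CL")

N_REWIRES = 10  # random surrogates for the omega L_r term


def roi_signals(epoch: Epoch, layout: ROILayout) -> np.ndarray:
    """6 x samples matrix; each ROI series is the mean of its channels."""
    rows = []
    for roi in NODE_ORDER:
        chans = layout.rois[roi]
        if not chans:
            raise ValueError(f"ROI {roi} has no channels")
        rows.append(epoch.channel_rows(chans).mean(axis=0))
    return np.vstack(rows)


def imag_coherency(epoch: Epoch, layout: ROILayout) -> Dict[str, np.ndarray]:
    """Band-wise 6x6 connectivity matrices w_ij = mean over band bins of
    |Im(S_ij / sqrt(S_ii S_jj))|, with Welch cross-spectra estimated on
    2-s Hamming segments without overlap (as for the PSD features)."""
    x = roi_signals(epoch, layout)
    nperseg = int(round(WELCH_SEGMENT_S * epoch.fs))
    freqs, sxx = sps.welch(x, fs=epoch.fs, window="hamming",
                           nperseg=nperseg, noverlap=0, detrend="constant")
    _, sxy = sps.csd(x[:, None, :], x[None, :, :], fs=epoch.fs,
                     window="hamming", nperseg=nperseg, noverlap=0,
                     detrend="constant")
    out: Dict[str, np.ndarray] = {}
    for band in BAND_ORDER:
        mask = band_mask(freqs, band)
        if np.any(sxx[:, mask].sum(axis=1) <= 0):
            raise FeatureError(f"zero auto-spectrum in {band} band")
        denom = np.sqrt(sxx[:, None, mask] * sxx[None, :, mask])
        coh = np.abs(np.imag(sxy[:, :, mask] / denom)).mean(axis=2)
        np.fill_diagonal(coh, 0.0)
        out[band] = 0.5 * (coh + coh.T)  # enforce exact symmetry
    return out


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


@dataclass
class PrunedGraph:
    """Sparse 6-node graph after proportional thresholding."""

    weights: np.ndarray     # 6x6 symmetric, zeros for removed edges
    percentile: int         # largest p (1% steps) that kept connectivity
    fallback: bool = False  # True if no threshold yields a connected graph

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    masks = [int(np.packbits(adj[i], bitorder="little")[0]) for i in range(n)]
    seen = 1
    frontier = 1
    while frontier:
        nxt = 0
        f = frontier
        while f:
            b = f & -f
            nxt |= masks[b.bit_length() - 1]
            f ^= b
        frontier = nxt & ~seen
        seen |= frontier
    return seen == (1 << n) - 1


def prune_graph(cm: np.ndarray) -> PrunedGraph:
    """Retain edges with weight >= the p-th percentile of the 15
    off-diagonal weights, for the largest p in {99, 98, ..., 0} that
    keeps all six nodes connected.  Ties at the threshold are retained.
    If no threshold connects the graph (zero-weight pattern), fall back
    to keeping every positive edge and set the fallback flag.

    Lowering p only adds edges, so connectivity is monotone in p and the
    scan reduces to a binary search for the largest connected percentile.
    """
    W = np.asarray(cm, dtype=float)
    iu = np.triu_indices_from(W, k=1)
    off = W[iu]
    thresholds = np.percentile(off, np.arange(100))

    def keep_at(p: int) -> np.ndarray:
        keep = (W >= thresholds[p]) & (W > 0)
        np.fill_diagonal(keep, False)
        return keep

    if not _is_connected(keep_at(0)):
        keep = W > 0
        np.fill_diagonal(keep, False)
        return PrunedGraph(weights=np.where(keep, W, 0.0), percentile=0, fallback=True)
    lo, hi = 0, 99  # lo: connected, hi+1: known disconnected
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _is_connected(keep_at(mid)):
            lo = mid
        else:
            hi = mid - 1
    keep = keep_at(lo)
    return PrunedGraph(weights=np.where(keep, W, 0.0), percentile=lo)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def shortest_path_lengths(W: np.ndarray) -> np.ndarray:
    """All-pairs weighted distances with edge length 1/w (Floyd-Warshall)."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    pos = W > 0
    D[pos] = 1.0 / W[pos]
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    return D


def onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering coefficient (geometric-mean form,
    weights normalized by the network maximum)."""
    wmax = W.max()
    if wmax <= 0:
        return np.zeros(W.shape[0])
    c = np.cbrt(W / wmax)
    num = np.diagonal(c @ c @ c)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(W.shape[0])
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return out


def _rewired_surrogate(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving, connectivity-preserving random rewiring; edge
    weights travel with the rewired edges."""
    A = W.copy()
    n = A.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j] > 0]
    m = len(edges)
    if m < 2:
        return A
    attempts = 10 * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts)
    for (e1, e2), fl in zip(pick, flip):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if fl < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if A[a, d] > 0 or A[c, b] > 0:
            continue
        wab, wcd = A[a, b], A[c, d]
        A[a, b] = A[b, a] = 0.0
        A[c, d] = A[d, c] = 0.0
        A[a, d] = A[d, a] = wab
        A[c, b] = A[b, c] = wcd
        if _is_connected(A > 0):
            edges[e1] = (min(a, d), max(a, d))
            edges[e2] = (min(c, b), max(c, b))
        else:  # revert
            A[a, d] = A[d, a] = 0.0
            A[c, b] = A[b, c] = 0.0
            A[a, b] = A[b, a] = wab
            A[c, d] = A[d, c] = wcd
    return A


def _lattice_surrogate(W: np.ndarray) -> np.ndarray:
    """Deterministic ring-lattice rearrangement of the weight multiset:
    edge slots ordered by ring distance (nearest neighbours first) receive
    the weights in descending order."""
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = np.sort(W[iu])[::-1]
    weights = weights[weights > 0]
    slots = sorted(
        zip(*iu), key=lambda e: (min(abs(e[0] - e[1]), n - abs(e[0] - e[1])), e)
    )
    L = np.zeros_like(W)
    for w, (i, j) in zip(weights, slots):
        L[i, j] = L[j, i] = w
    return L


def graph_metrics(g: PrunedGraph, rng: np.random.Generator) -> Dict[str, float]:
    """Global metrics of a pruned (connected) graph.

    omega = L_r/L_w - C_w/C_l compares the graph against random and
    lattice surrogates; near 0 indicates a small-world regime.  When the
    lattice surrogate is triangle-free (C_l = 0) the clustering ratio is
    capped at 1 (0 if the graph itself has no triangles).
    """
    W = g.weights
    n = g.n_nodes
    if not _is_connected(W > 0):
        raise ValueError("graph_metrics requires a connected graph")
    deg = (W > 0).sum(axis=1).astype(float)
    strength = W.sum(axis=1)
    D = shortest_path_lengths(W)
    iu = np.triu_indices(n, k=1)
    L_w = float(D[iu].mean())
    C_w = float(onnela_clustering(W).mean())
    L_r = float(
        np.mean(
            [shortest_path_lengths(_rewired_surrogate(W, rng))[iu].mean()
             for _ in range(N_REWIRES)]
        )
    )
    C_l = float(onnela_clustering(_lattice_surrogate(W)).mean())
    if C_l > 0:
        c_ratio = C_w / C_l
    else:
        c_ratio = 0.0 if C_w == 0 else 1.0
    omega = L_r / L_w - c_ratio
    # rich nodes: strength above the 75th percentile of node strengths
    thr = np.percentile(strength, 75)
    rich = strength > thr
    rc_terms = np.zeros(n)
    for i in range(n):
        if strength[i] > 0:
            rc_terms[i] = ((W[i] > 0) & rich).sum() / strength[i]
    return {
        "degree": float(deg.mean()),
        "strength": float(strength.mean()),
        "pathlen": L_w,
        "clustering": C_w,
        "omega": float(omega),
        "richclub": float(rc_terms.mean()),
    }


def nodal_metrics(g: PrunedGraph, node: int) -> Dict[str, float]:
    """Degree, strength, path length, clustering and local efficiency of
    one node.  Nodal path length is the mean distance to the other
    nodes; local efficiency is the mean inverse distance within the
    subgraph induced by the node's neighbours."""
    W = g.weights
    n = g.n_nodes
    D = shortest_path_lengths(W)
    others = [j for j in range(n) if j != node]
    neigh = np.nonzero(W[node])[0]
    if len(neigh) >= 2:
        sub = W[np.ix_(neigh, neigh)]
        Dsub = shortest_path_lengths(sub)
        iu = np.triu_indices(len(neigh), k=1)
        inv = np.where(np.isfinite(Dsub[iu]), 1.0 / Dsub[iu], 0.0)
        local_eff = float(inv.mean())
    else:
        local_eff = 0.0
    return {
        "degree": float((W[node] > 0).sum()),
        "strength": float(W[node].sum()),
        "pathlen": float(D[node, others].mean()),
        "clustering": float(onnela_clustering(W)[node]),
        "localeff": local_eff,
    }


# ---------------------------------------------------------------------------
# Feature block
# ---------------------------------------------------------------------------

_GLOBAL = ("degree", "strength", "pathlen", "clustering", "omega", "richclub")
_NODAL = ("degree", "strength", "pathlen", "clustering", "localeff")


def _build_names() -> list:
    names = []
    for band in BAND_ORDER:
        for metric in _GLOBAL:
            names.append(f"net_{metric}_{band}")
        for metric in _NODAL:
            for side in ("AH", "UH"):
                names.append(f"node_{metric}_{band}_{side}")
    return names


CONNECTIVITY_FEATURE_NAMES: Tuple[str, ...] = tuple(_build_names())
assert len(CONNECTIVITY_FEATURE_NAMES) == 80


def connectivity_block(
    epoch: Epoch, layout: ROILayout, seed: int = 0
) -> Dict[str, float]:
    """All 80 connectivity/network features of one epoch.  The seed fixes
    the random rewiring stream of the omega surrogates, making the block
    deterministic."""
    matrices = imag_coherency(epoch, layout)
    rng = np.random.default_rng(seed)
    out: Dict[str, float] = {}
    for band in BAND_ORDER:
        g = prune_graph(matrices[band])
        gm = graph_metrics(g, rng)
        for metric in _GLOBAL:
            out[f"net_{metric}_{band}"] = gm[metric]
        nm = {"AH": nodal_metrics(g, _AH_NODE), "UH": nodal_metrics(g, _UH_NODE)}
        for metric in _NODAL:
            for side in ("AH", "UH"):
                out[f"node_{metric}_{band}_{side}"] = nm[side][metric]
    assert tuple(out) == CONNECTIVITY_FEATURE_NAMES
    return out
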
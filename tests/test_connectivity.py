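"""Imaginary coherency, proportional-threshold pruning and graph metrics.

Brute-force oracles (pure-python shortest paths, direct triple counting,
exhaustive threshold enumeration) and networkx serve as independent
references for the package's own metric implementations.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from strokerecovnet.connectivity import (
    CONNECTIVITY_FEATURE_NAMES,
    NODE_ORDER,
    PrunedGraph,
    _lattice_surrogate,
    connectivity_block,
    graph_metrics,
    imag_coherency,
    nodal_metrics,
    onnela_clustering,
    prune_graph,
    roi_signals,
    shortest_path_lengths,
)
from strokerecovnet.core import ROI_CHANNELS

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_distances(W):
    """Dijkstra via networkx on the 1/w length graph."""
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i, lengths in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for j, d in lengths.items():
            D[i, j] = d
    return D


def oracle_clustering(W):
    """Direct Onnela triple counting (normalized by the max weight)."""
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += ((W[i, j] / wmax) * (W[i, h] / wmax) * (W[j, h] / wmax)) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out


def oracle_prune_percentile(W):
    """Exhaustive scan of every percentile threshold (reference definition)."""
    iu = np.triu_indices_from(W, k=1)
    off = W[iu]
    for p in range(99, -1, -1):
        thr = np.percentile(off, p)
        keep = (W >= thr) & (W > 0)
        np.fill_diagonal(keep, False)
        G = nx.from_numpy_array(keep.astype(float))
        if nx.is_connected(G):
            return p
    return None


def random_connected_weights(rng, density=1.0):
    while True:
        W = np.zeros((6, 6))
        iu = np.triu_indices(6, k=1)
        w = rng.uniform(0.05, 1.0, size=15) * (rng.random(15) < density)
        W[iu] = w
        W += W.T
        if nx.is_connected(nx.from_numpy_array((W > 0).astype(float))):
            return W


# ---------------------------------------------------------------------------
# ROI signals and coherency
# ---------------------------------------------------------------------------


class TestRoiSignals:
    def test_identical_channels_pass_through(self, epoch_factory, layout):
        ep = epoch_factory(lambda ch, t: np.sin(2 * np.pi * 3 * t))
        sig = roi_signals(ep, layout)
        np.testing.assert_allclose(sig[0], np.sin(2 * np.pi * 3 * np.arange(2560) / 256.0), atol=1e-12)

    def test_opposite_channels_cancel(self, epoch_factory, layout):
        fr = ROI_CHANNELS["FR"]

        def fn(ch, t):
            if ch in fr:
                sign = 1.0 if fr.index(ch) % 2 == 0 else -1.0
                return sign * np.sin(2 * np.pi * 5 * t)
            return np.zeros_like(t)

        # 7 channels: 4 positive, 3 negative -> mean = sin/7
        sig = roi_signals(epoch_factory(fn), layout)
        assert np.abs(sig[0]).max() == pytest.approx(1 / 7, abs=1e-9)

    def test_linearity(self, epoch_factory, layout):
        rng = np.random.default_rng(0)
        a = {ch: rng.standard_normal(2560) for roi in ROI_CHANNELS.values() for ch in roi}
        b = {ch: rng.standard_normal(2560) for roi in ROI_CHANNELS.values() for ch in roi}
        ea = epoch_factory(lambda ch, t: a[ch])
        eb = epoch_factory(lambda ch, t: b[ch])
        eab = epoch_factory(lambda ch, t: a[ch] + b[ch])
        np.testing.assert_allclose(
            roi_signals(eab, layout),
            roi_signals(ea, layout) + roi_signals(eb, layout),
            atol=1e-10,
        )


class TestImagCoherency:
    def test_identical_signals_give_zero(self, epoch_factory, layout):
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(2560)
        mats = imag_coherency(epoch_factory(lambda ch, t: shared), layout)
        for band, W in mats.items():
            assert W.max() < 0.05

    def test_quadrature_pair_saturates_alpha(self, epoch_factory, layout):
        """A 90-degree-shifted (Hilbert quadrature) copy has |Im coh| ~ 1
        at every frequency, so the alpha band weight saturates."""
        from scipy.signal import hilbert

        rng = np.random.default_rng(2)
        x = rng.standard_normal(2560)
        xq = np.imag(hilbert(x))
        cr, cl = ROI_CHANNELS["CR"], ROI_CHANNELS["CL"]

        def fn(ch, t):
            noise = 0.01 * rng.standard_normal(t.size)
            if ch in cr:
                return x + noise
            if ch in cl:
                return xq + noise
            return rng.standard_normal(t.size)

        W = imag_coherency(epoch_factory(fn), layout)["alpha"]
        i, j = NODE_ORDER.index("CR"), NODE_ORDER.index("CL")
        assert W[i, j] > 0.9

    def test_independent_noise_stays_low(self, epoch_factory, layout):
        """5-segment Welch gives an |Im coh| bias of ~0.25 per bin for
        independent signals; band means over pairs stay below 0.3 and
        every individual weight stays well below genuine coupling."""
        rng = np.random.default_rng(3)
        mats = imag_coherency(
            epoch_factory(lambda ch, t: rng.standard_normal(t.size)), layout
        )
        iu = np.triu_indices(6, 1)
        for band, W in mats.items():
            assert W[iu].mean() < 0.3
            assert W.max() < 0.5

    def test_scale_invariance(self, epoch_factory, layout):
        rng = np.random.default_rng(4)
        sigs = {ch: rng.standard_normal(2560) for roi in ROI_CHANNELS.values() for ch in roi}
        m1 = imag_coherency(epoch_factory(lambda ch, t: sigs[ch]), layout)
        m2 = imag_coherency(epoch_factory(lambda ch, t: 7.5 * sigs[ch]), layout)
        for band in m1:
            np.testing.assert_allclose(m1[band], m2[band], atol=1e-10)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


class TestPruning:
    def test_star_graph_survives(self):
        W = np.zeros((6, 6))
        W[0, 1:] = W[1:, 0] = 0.8
        g = prune_graph(W)
        assert not g.fallback
        assert (g.weights > 0).sum() == 10  # 5 undirected edges

    def test_all_equal_weights_keep_everything_at_99(self):
        W = np.full((6, 6), 0.5)
        np.fill_diagonal(W, 0.0)
        g = prune_graph(W)
        assert g.percentile == 99
        assert (g.weights > 0).sum() == 30

    def test_matches_exhaustive_threshold_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            W = random_connected_weights(rng, density=rng.uniform(0.5, 1.0))
            g = prune_graph(W)
            assert g.percentile == oracle_prune_percentile(W)

    def test_disconnected_pattern_falls_back(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 1.0  # two components no threshold can join
        W[2, 3] = W[3, 2] = 1.0
        g = prune_graph(W)
        assert g.fallback and g.percentile == 0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def complete_graph(w=1.0):
    W = np.full((6, 6), w)
    np.fill_diagonal(W, 0.0)
    return PrunedGraph(weights=W, percentile=0)


class TestGraphMetrics:
    def test_complete_unit_graph(self):
        gm = graph_metrics(complete_graph(), np.random.default_rng(0))
        assert gm["degree"] == 5.0
        assert gm["strength"] == 5.0
        assert gm["pathlen"] == pytest.approx(1.0)
        assert gm["clustering"] == pytest.approx(1.0)
        assert gm["richclub"] == 0.0  # equal strengths: no node above P75

    def test_embedded_path_distances_match_dijkstra(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        D = shortest_path_lengths(W)
        np.testing.assert_allclose(D[:3, :3], oracle_distances(W)[:3, :3])
        assert D[0, 2] == pytest.approx(2.0)
        assert np.isinf(D[0, 3])

    def test_deterministic_omega_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        W = random_connected_weights(rng)
        g = prune_graph(W)
        m1 = graph_metrics(g, np.random.default_rng(42))
        m2 = graph_metrics(g, np.random.default_rng(42))
        assert m1["omega"] == m2["omega"]

    def test_omega_zero_on_complete_unit_graph(self):
        # L_r = L_w = 1 and C_w = C_l = 1, so both ratios cancel exactly
        gm = graph_metrics(complete_graph(), np.random.default_rng(3))
        assert gm["omega"] == pytest.approx(0.0)

    def test_omega_scale_invariant(self):
        """Common weight scaling cancels in both the path-length ratio and
        the max-normalized clustering ratio."""
        rng = np.random.default_rng(6)
        W = random_connected_weights(rng)
        g1 = PrunedGraph(W, 0)
        g2 = PrunedGraph(4.2 * W, 0)
        om1 = graph_metrics(g1, np.random.default_rng(9))["omega"]
        om2 = graph_metrics(g2, np.random.default_rng(9))["omega"]
        assert om1 == pytest.approx(om2)

    def test_lattice_surrogate_reproduces_ring_lattice(self):
        """When the graph already is a ring lattice (heavy near weights,
        light far weights), the deterministic lattice rearrangement must
        return the same clustering, i.e. C_l = C_w."""
        n = 6
        ring = np.zeros((n, n))
        for i in range(n):
            for d, w in ((1, 1.0), (2, 0.2)):
                j = (i + d) % n
                ring[i, j] = ring[j, i] = w
        lat = _lattice_surrogate(ring)
        np.testing.assert_allclose(
            np.sort(onnela_clustering(lat)), np.sort(onnela_clustering(ring))
        )

    def test_disconnected_input_rejected(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="connected"):
            graph_metrics(PrunedGraph(W, 0), np.random.default_rng(0))


class TestNodalMetrics:
    def test_star_leaf(self):
        W = np.zeros((6, 6))
        W[0, 1:] = W[1:, 0] = 1.0
        nm = nodal_metrics(PrunedGraph(W, 0), node=1)
        assert nm["clustering"] == 0.0
        assert nm["localeff"] == 0.0
        assert nm["degree"] == 1.0

    def test_unit_triangle_clustering(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5)]:
            W[i, j] = W[j, i] = 1.0
        nm = nodal_metrics(PrunedGraph(W, 0), node=0)
        assert nm["clustering"] == pytest.approx(1.0)

    def test_random_graphs_match_oracles(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            W = random_connected_weights(rng, density=rng.uniform(0.5, 1.0))
            g = PrunedGraph(W, 0)
            D_o = oracle_distances(W)
            C_o = oracle_clustering(W)
            Gx = nx.from_numpy_array(W)
            C_nx = nx.clustering(Gx, weight="weight")
            for node in range(6):
                nm = nodal_metrics(g, node)
                others = [j for j in range(6) if j != node]
                assert nm["pathlen"] == pytest.approx(D_o[node, others].mean())
                assert nm["clustering"] == pytest.approx(C_o[node])
                assert nm["clustering"] == pytest.approx(C_nx[node])
                assert nm["degree"] == (W[node] > 0).sum()
                assert nm["strength"] == pytest.approx(W[node].sum())
                # local efficiency oracle: mean inverse distance among neighbours
                neigh = np.nonzero(W[node])[0]
                if len(neigh) >= 2:
                    Dn = oracle_distances(W[np.ix_(neigh, neigh)])
                    iu = np.triu_indices(len(neigh), 1)
                    inv = np.where(np.isfinite(Dn[iu]), 1.0 / Dn[iu], 0.0)
                    assert nm["localeff"] == pytest.approx(inv.mean())


class TestConnectivityBlock:
    def test_80_named_features(self, tiny_cohort, layout):
        from strokerecovnet.core import extract_epochs, swap_hemispheres

        rec = swap_hemispheres(next(iter(tiny_cohort.recordings.values())))
        ep = extract_epochs(rec)[0]
        block = connectivity_block(ep, layout, seed=0)
        assert len(block) == 80
        assert tuple(block) == CONNECTIVITY_FEATURE_NAMES
        assert all(np.isfinite(v) for v in block.values())

    def test_fixed_seed_reproducible(self, tiny_cohort, layout):
        from strokerecovnet.core import extract_epochs, swap_hemispheres

        rec = swap_hemispheres(next(iter(tiny_cohort.recordings.values())))
        ep = extract_epochs(rec)[0]
        b1 = connectivity_block(ep, layout, seed=3)
        b2 = connectivity_block(ep, layout, seed=3)
        assert b1 == b2

    def test_hemisphere_swap_exchanges_nodal_features(self, epoch_factory, layout):
        rng = np.random.default_rng(8)
        sigs = {}
        from strokerecovnet.core import homologue

        for roi in ROI_CHANNELS.values():
            for ch in roi:
                sigs[ch] = rng.standard_normal(2560)

        def swapped_fn(ch, t):
            return sigs[homologue(ch)]

        b1 = connectivity_block(epoch_factory(lambda ch, t: sigs[ch]), layout, seed=0)
        b2 = connectivity_block(epoch_factory(swapped_fn), layout, seed=0)
        for band in ("alpha", "beta"):
            for metric in ("degree", "strength", "pathlen", "clustering", "localeff"):
                assert b1[f"node_{metric}_{band}_AH"] == pytest.approx(
                    b2[f"node_{metric}_{band}_UH"], rel=1e-9
                )
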
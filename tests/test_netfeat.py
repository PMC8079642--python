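"""Pair-level predictors: HG integrals, PCA windows, centrality, CCEP terms."""

import warnings

import networkx as nx
import numpy as np
import pytest

from stimmap.ccep import CCEPGraph, CCEPRecord, build_graph
from stimmap.netfeat import (
    ActivationSummary,
    assemble_features,
    hg_correlation_network,
    integrate_hg_alltime,
    integrate_hg_pca,
    pagerank_centrality,
    pca_windows,
    summarize_activation,
)
from stimmap.stfm import HGSeries, SignificanceMap


BINS = np.arange(-62, 125) * 16.0  # -992 .. 1984 ms


def _hg(values):
    return HGSeries(values=values, bin_centers_ms=BINS)


def _map(t, mask, baseline_mean=None):
    n_ch, n_bins = t.shape
    return SignificanceMap(
        t_values=t,
        p_values=np.where(mask, 0.001, 0.5),
        fdr_mask=mask,
        stfm_positive=np.any(mask & (t > 0), axis=1),
        baseline_mean=np.zeros(n_ch) if baseline_mean is None else baseline_mean,
        bin_centers_ms=BINS,
    )


class TestIntegration:
    def test_constructed_deviation_sums_exactly(self):
        # 25 masked bins each +0.4 above baseline -> 10.0
        n_ch, n_tr = 3, 4
        vals = np.ones((n_ch, n_tr, BINS.size))
        post = np.flatnonzero(BINS > 0)[:25]
        vals[0][:, post] += 0.4
        t = np.zeros((n_ch, BINS.size))
        mask = np.zeros_like(t, dtype=bool)
        t[0, post] = 5.0
        mask[0, post] = True
        out = integrate_hg_alltime(_map(t, mask, np.ones(n_ch)), _hg(vals))
        assert abs(out[0] - 10.0) < 1e-9
        assert np.all(out[1:] == 0.0)

    def test_no_masked_bins_gives_zero(self):
        vals = np.random.default_rng(0).normal(size=(2, 3, BINS.size))
        t = np.zeros((2, BINS.size))
        out = integrate_hg_alltime(_map(t, np.zeros_like(t, dtype=bool)), _hg(vals))
        assert np.all(out == 0.0)

    def test_pca_integral_never_exceeds_alltime(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 6, BINS.size)) + 0.5
        t = rng.normal(size=(4, BINS.size)) + 1.0
        mask = rng.uniform(size=t.shape) < 0.3
        sm = _map(t, mask)
        selected = rng.uniform(size=BINS.size) < 0.5
        all_t = integrate_hg_alltime(sm, _hg(vals))
        pca_t = integrate_hg_pca(sm, _hg(vals), selected)
        assert np.all(pca_t <= all_t + 1e-12)

    def test_misaligned_grids_rejected(self):
        vals = np.zeros((2, 3, BINS.size))
        t = np.zeros((2, BINS.size - 1))
        sm = SignificanceMap(
            t_values=t, p_values=t, fdr_mask=t.astype(bool),
            stfm_positive=np.zeros(2, bool), baseline_mean=np.zeros(2),
            bin_centers_ms=BINS[:-1],
        )
        with pytest.raises(ValueError, match="grids differ"):
            integrate_hg_alltime(sm, _hg(vals))


class TestPCAWindows:
    def test_shared_burst_selects_its_support(self):
        rng = np.random.default_rng(0)
        env = np.exp(-((BINS - 400.0) ** 2) / (2 * 80.0**2))
        vals = np.zeros((4, 2, BINS.size))
        for c in range(4):
            vals[c] += 2.0 * env + 0.01 * rng.normal(size=BINS.size)
        sel = pca_windows(_hg(vals), [True] * 4)
        sel_ms = BINS[sel]
        assert sel_ms.min() >= 200.0 - 33 and sel_ms.max() <= 600.0 + 33
        assert sel_ms.size >= 5

    def test_two_disjoint_bursts_select_union(self):
        rng = np.random.default_rng(1)
        env1 = np.exp(-((BINS - 300.0) ** 2) / (2 * 50.0**2))
        env2 = np.exp(-((BINS - 1400.0) ** 2) / (2 * 50.0**2))
        vals = 0.01 * rng.normal(size=(4, 2, BINS.size))
        vals[:2] += 2.0 * env1
        vals[2:] += 2.0 * env2
        sel_ms = BINS[pca_windows(_hg(vals), [True] * 4)]
        assert ((sel_ms > 150) & (sel_ms < 450)).any()
        assert ((sel_ms > 1250) & (sel_ms < 1550)).any()

    def test_degenerate_covariance_falls_back_with_warning(self):
        vals = np.ones((3, 2, BINS.size))
        with pytest.warns(UserWarning, match="degenerate|constant"):
            sel = pca_windows(_hg(vals), [True] * 3)
        assert np.array_equal(sel, BINS > 0)

    def test_single_positive_channel_falls_back(self):
        vals = np.random.default_rng(2).normal(size=(3, 2, BINS.size))
        with pytest.warns(UserWarning, match="fewer than 2"):
            sel = pca_windows(_hg(vals), [True, False, False])
        assert np.array_equal(sel, BINS > 0)


class TestCorrelationNetwork:
    def test_identical_courses_weight_one_no_self_edges(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=BINS.size)
        vals = np.stack([np.tile(base, (2, 1)), np.tile(base, (2, 1))])
        g = hg_correlation_network(_hg(vals), [True, True])
        assert not any(a == b for a, b in g.edges)
        assert g[0][1]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_pair_clipped_to_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=BINS.size)
        vals = np.stack([np.tile(base, (2, 1)), np.tile(-base, (2, 1))])
        g = hg_correlation_network(_hg(vals), [True, True])
        assert g.number_of_edges() == 0

    def test_zero_variance_channel_warns(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(3, 2, BINS.size))
        vals[1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            g = hg_correlation_network(_hg(vals), [True] * 3)
        assert g.degree(1) == 0


def pagerank_power_iteration(graph, damping=0.85, tol=1e-14):
    """Independent oracle: dense power iteration on the Google matrix."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    W = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        ia, ib = nodes.index(a), nodes.index(b)
        W[ia, ib] = w
        W[ib, ia] = w
    rowsum = W.sum(axis=1)
    P = np.where(rowsum[:, None] > 0, W / np.maximum(rowsum[:, None], 1e-300), 1.0 / n)
    v = np.full(n, 1.0 / n)
    for _ in range(10_000):
        nxt = damping * (P.T @ v) + (1 - damping) / n
        if np.abs(nxt - v).max() < tol:
            break
        v = nxt
    return dict(zip(nodes, v / v.sum()))


class TestPageRank:
    def test_complete_graph_uniform(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        scores = pagerank_centrality(g, n_channels=5)
        np.testing.assert_allclose(scores, 0.2, atol=1e-10)

    def test_path_graph_center_dominates(self):
        g = nx.path_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        s = pagerank_centrality(g, n_channels=3)
        assert s[1] > s[0] == pytest.approx(s[2], abs=1e-12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.Graph()
            g.add_nodes_from(range(6))
            for a in range(6):
                for b in range(a + 1, 6):
                    if rng.uniform() < 0.6:
                        g.add_edge(a, b, weight=float(rng.uniform(0.1, 2.0)))
            scores = pagerank_centrality(g, n_channels=6)
            oracle = pagerank_power_iteration(g)
            for node, val in oracle.items():
                assert abs(scores[node] - val) < 1e-10

    def test_empty_graph_warns_all_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            scores = pagerank_centrality(nx.Graph(), n_channels=4)
        assert np.all(scores == 0.0)


class TestAssemble:
    def _activation(self, hg_alltime, hg_pca, centrality):
        return ActivationSummary(
            hg_alltime=np.asarray(hg_alltime, float),
            hg_pca=np.asarray(hg_pca, float),
            centrality=np.asarray(centrality, float),
            selected_bins=np.ones(5, bool),
            stfm_positive=np.asarray(hg_alltime, float) > 0,
        )

    def _graph(self, pair, zs, channels):
        rec = CCEPRecord(
            stim_pair=pair,
            channels=np.asarray(channels),
            mean_waveforms=np.zeros((len(channels), 4)),
            times_ms=np.arange(4.0),
            n1_latency_ms=np.full(len(channels), 20.0),
            n1_z=np.asarray(zs, float),
            significant=np.asarray(zs, float) > 6.0,
        )
        return build_graph([rec])

    def test_squared_sum_arithmetic(self):
        act = self._activation([1, 2, 3, 0], [0, 2, 3, 0], [0, 0.5, 0.5, 0])
        feats = assemble_features(
            ["b-c"], {"b-c": (1, 2)}, act, {"b-c": 1}
        )
        row = feats.iloc[0]
        assert row.f_alltime == 4 + 9
        assert row.f_pca == 4 + 9
        assert row.f_centrality == 0.25 + 0.25
        assert np.isnan(row.f_ccep_z)

    def test_inactive_pair_zero_propagation(self):
        act = self._activation([0, 0, 3, 4], [0, 0, 2, 3], [0, 0, 0.5, 0.5])
        g = self._graph("a-b", [1.0, 2.0], [2, 3])
        feats = assemble_features(["a-b"], {"a-b": (0, 1)}, act, {"a-b": 0}, g)
        row = feats.iloc[0]
        assert row.f_alltime == 0 and row.f_pca == 0 and row.f_centrality == 0
        assert row.f_ccep_edges == 0.0  # no significant edges

    def test_ccep_features_follow_connectivity(self):
        act = self._activation([1, 1, 5, 5], [1, 1, 4, 4], [0.25] * 4)
        strong = self._graph("a-b", [10.0, 10.0], [2, 3])
        weak = self._graph("c-d", [0.5, 0.5], [0, 1])
        feats_s = assemble_features(["a-b"], {"a-b": (0, 1)}, act, {"a-b": 1}, strong)
        feats_w = assemble_features(["c-d"], {"c-d": (2, 3)}, act, {"c-d": 0}, weak)
        assert feats_s.iloc[0].f_ccep_z > feats_w.iloc[0].f_ccep_z
        # z-weighted term: (10*4 + 10*4)/4 channels
        assert feats_s.iloc[0].f_ccep_z == pytest.approx(20.0)
        assert feats_s.iloc[0].f_ccep_edges == pytest.approx(2 * 10 / 4)

    def test_unknown_channel_rejected(self):
        act = self._activation([1, 1], [1, 1], [0.5, 0.5])
        with pytest.raises(ValueError, match="unknown channel"):
            assemble_features(["a-x"], {"a-x": (0, 7)}, act, {"a-x": 0})

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(0)
        n = 6
        hg_a, hg_p = rng.uniform(0, 3, n), rng.uniform(0, 2, n)
        cent = rng.dirichlet(np.ones(n))
        act = ActivationSummary(hg_a, hg_p, cent, np.ones(3, bool), hg_a > 0)
        pairs = {"p0": (0, 1), "p1": (2, 3)}
        feats = assemble_features(list(pairs), pairs, act, {"p0": 1, "p1": 0})
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        act2 = ActivationSummary(
            hg_a[perm], hg_p[perm], cent[perm], np.ones(3, bool), hg_a[perm] > 0
        )
        pairs2 = {k: (inv[i], inv[j]) for k, (i, j) in pairs.items()}
        feats2 = assemble_features(list(pairs2), pairs2, act2, {"p0": 1, "p1": 0})
        for col in ("f_alltime", "f_pca", "f_centrality"):
            np.testing.assert_allclose(feats[col], feats2[col])


class TestSummarize:
    def test_centrality_conservation_and_ordering(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(5, 30, BINS.size))
        env = np.exp(-((BINS - 500.0) ** 2) / (2 * 100.0**2))
        vals[1] += 3.0 * env
        vals[3] += 3.0 * env
        from stimmap.stfm import significance_map

        hg = _hg(vals)
        sm = significance_map(hg)
        act = summarize_activation(sm, hg)
        assert act.centrality.sum() == pytest.approx(1.0)
        assert np.all(act.centrality[~sm.stfm_positive] == 0.0)
        assert np.all(act.hg_pca <= act.hg_alltime + 1e-12)
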
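"""Per-pair predictors: integrated high gamma, PCA windows, centrality,
and the CCEP-weighted network terms.

For a stimulated pair the five candidate predictors are

* ``f_alltime``  = Σ over the pair's two electrodes of HG_alltime²
* ``f_pca``      = Σ over the pair of HG_pca²
* ``f_centrality`` = Σ over the pair of PageRank² (HG correlation network)
* ``f_ccep_z``   = Σ over all analyzable electrodes of (N1 z × HG_pca) / n_electrodes
* ``f_ccep_edges`` = significant-edge count of the pair × Σ HG_pca / n_electrodes

HG_alltime integrates the significant positive log-power deviation over
all post-stimulus bins; HG_pca restricts the same sum to bins selected
by principal component analysis of the trial-averaged high-gamma time
courses. PageRank centrality (damping 0.85) is computed on the graph of
positive Pearson correlations between STFM+ sites' high-gamma envelopes
and is 0 for STFM− sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ccep import CCEPGraph
from .stfm import HGSeries, SignificanceMap


@dataclass
class ActivationSummary:
    """Per-channel activation and centrality measures."""

    hg_alltime: np.ndarray
    hg_pca: np.ndarray
    centrality: np.ndarray
    selected_bins: np.ndarray  # bool over bins (PCA windows)
    stfm_positive: np.ndarray


def _aligned(sig_map: SignificanceMap, hg: HGSeries):
    if sig_map.t_values.shape != (hg.n_channels, hg.bin_centers_ms.size) or not np.allclose(
        sig_map.bin_centers_ms, hg.bin_centers_ms
    ):
        raise ValueError("significance map and HG series bin grids differ")


def integrate_hg_alltime(sig_map: SignificanceMap, hg: HGSeries) -> np.ndarray:
    """Summed significant positive log-power deviation, post-stimulus bins."""
    _aligned(sig_map, hg)
    trial_mean = hg.values.mean(axis=1)  # (channels, bins)
    dev = trial_mean - sig_map.baseline_mean[:, None]
    use = sig_map.fdr_mask & (sig_map.t_values > 0) & hg.poststim_mask[None, :]
    out = np.where(use, dev, 0.0).sum(axis=1)
    out[~sig_map.stfm_positive] = 0.0
    return out


def pca_windows(
    hg: HGSeries,
    stfm_positive,
    variance_fraction: float = 0.8,
    score_fraction: float = 0.5,
) -> np.ndarray:
    """Select post-stimulus time bins carrying the dominant HG dynamics.

    Principal components are computed across STFM+ channels (channels =
    variables, post-stimulus bins = observations, per-channel centering)
    on trial-averaged time courses. The smallest component set
    explaining ≥ ``variance_fraction`` of variance is retained; a bin is
    selected when any retained component's absolute temporal score
    reaches ``score_fraction`` of that component's maximum.

    Returns a boolean mask over *all* bins (False on baseline bins).
    Falls back to all post-stimulus bins (with a warning) when fewer
    than 2 STFM+ channels exist or the covariance is degenerate.
    """
    stfm_positive = np.asarray(stfm_positive, dtype=bool)
    post = hg.poststim_mask
    out = np.zeros(hg.bin_centers_ms.size, dtype=bool)
    chans = np.flatnonzero(stfm_positive)
    if chans.size < 2:
        warnings.warn("fewer than 2 STFM+ channels; using all post-stimulus bins")
        out[post] = True
        return out
    X = hg.values[chans].mean(axis=1)[:, post].T  # (bins, channels)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        warnings.warn("degenerate (constant) time courses; using all post-stimulus bins")
        out[post] = True
        return out
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, variance_fraction) + 1)
    scores = U[:, :k] * s[:k]  # temporal scores, (bins, k)
    sel = np.zeros(X.shape[0], dtype=bool)
    for comp in range(k):
        a = np.abs(scores[:, comp])
        sel |= a >= score_fraction * a.max()
    out[np.flatnonzero(post)[sel]] = True
    return out


def integrate_hg_pca(
    sig_map: SignificanceMap, hg: HGSeries, selected_bins
) -> np.ndarray:
    """Same integral as ``integrate_hg_alltime`` restricted to PCA bins."""
    _aligned(sig_map, hg)
    trial_mean = hg.values.mean(axis=1)
    dev = trial_mean - sig_map.baseline_mean[:, None]
    use = (
        sig_map.fdr_mask
        & (sig_map.t_values > 0)
        & hg.poststim_mask[None, :]
        & np.asarray(selected_bins, dtype=bool)[None, :]
    )
    out = np.where(use, dev, 0.0).sum(axis=1)
    out[~sig_map.stfm_positive] = 0.0
    return out


def hg_correlation_network(hg: HGSeries, stfm_positive) -> nx.Graph:
    """Positive-Pearson-correlation graph over STFM+ channels.

    Edge weight = max(0, r) between trial-averaged post-stimulus HG time
    courses; self-edges excluded; zero-variance channels keep their node
    but get no edges (warning).
    """
    chans = np.flatnonzero(np.asarray(stfm_positive, dtype=bool))
    if chans.size < 2:
        raise ValueError("need at least 2 STFM+ channels")
    X = hg.values[chans].mean(axis=1)[:, hg.poststim_mask]
    g = nx.Graph()
    g.add_nodes_from(int(c) for c in chans)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance HG time course(s); their edges set to 0")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X)
    for a in range(chans.size):
        for b in range(a + 1, chans.size):
            if sd[a] == 0 or sd[b] == 0:
                continue
            w = max(0.0, float(r[a, b]))
            if w > 0:
                g.add_edge(int(chans[a]), int(chans[b]), weight=w)
    return g


def pagerank_centrality(
    graph: nx.Graph, damping: float = 0.85, n_channels: int | None = None
) -> np.ndarray:
    """PageRank scores of the correlation network.

    Returns a vector over all channels (0 for channels outside the
    graph); scores sum to 1 over graph nodes. Dangling/isolated nodes
    receive the uniform teleport mass, as in the standard formulation.
    """
    if n_channels is None:
        n_channels = (max(graph.nodes) + 1) if graph.number_of_nodes() else 0
    out = np.zeros(n_channels)
    if graph.number_of_nodes() == 0:
        warnings.warn("empty graph; all centralities 0")
        return out
    pr = nx.pagerank(graph, alpha=damping, weight="weight", tol=1e-14, max_iter=1000)
    for node, score in pr.items():
        out[node] = score
    return out


def summarize_activation(
    sig_map: SignificanceMap,
    hg: HGSeries,
    damping: float = 0.85,
    variance_fraction: float = 0.8,
) -> ActivationSummary:
    """Full per-channel activation summary feeding the pair features."""
    hg_alltime = integrate_hg_alltime(sig_map, hg)
    stfm_pos = sig_map.stfm_positive
    selected = pca_windows(hg, stfm_pos, variance_fraction=variance_fraction)
    hg_pca = integrate_hg_pca(sig_map, hg, selected)
    if stfm_pos.sum() >= 2:
        graph = hg_correlation_network(hg, stfm_pos)
        centrality = pagerank_centrality(graph, damping, hg.n_channels)
    elif stfm_pos.sum() == 1:
        centrality = np.zeros(hg.n_channels)
        centrality[np.flatnonzero(stfm_pos)[0]] = 1.0
    else:
        centrality = np.zeros(hg.n_channels)
    return ActivationSummary(
        hg_alltime=hg_alltime,
        hg_pca=hg_pca,
        centrality=centrality,
        selected_bins=selected,
        stfm_positive=stfm_pos,
    )


def assemble_features(
    pairs,
    pair_indices,
    activation: ActivationSummary,
    esm_labels: dict,
    ccep_graph: CCEPGraph | None = None,
    analyzable: np.ndarray | None = None,
) -> pd.DataFrame:
    """One feature row per ESM-tested pair.

    Parameters
    ----------
    pairs : list of pair ids
    pair_indices : dict pair -> (i, j) channel indices
    esm_labels : dict pair -> {0, 1}
    ccep_graph : CCEPGraph or None
        Pairs absent from the graph get NaN CCEP features (they are
        excluded from CCEP-based model fits, not imputed).
    analyzable : bool mask of channels entering the Σ_grid sums;
        defaults to all channels in the activation summary.
    """
    n_ch = activation.hg_alltime.size
    if analyzable is None:
        analyzable = np.ones(n_ch, dtype=bool)
    analyzable = np.asarray(analyzable, dtype=bool)
    n_electrodes = int(analyzable.sum())
    rows = []
    for pair in pairs:
        i, j = pair_indices[pair]
        if not (0 <= i < n_ch and 0 <= j < n_ch):
            raise ValueError(f"pair {pair} references unknown channel")
        f_alltime = activation.hg_alltime[i] ** 2 + activation.hg_alltime[j] ** 2
        f_pca = activation.hg_pca[i] ** 2 + activation.hg_pca[j] ** 2
        f_cent = activation.centrality[i] ** 2 + activation.centrality[j] ** 2
        f_ccep_z = np.nan
        f_ccep_edges = np.nan
        if ccep_graph is not None and pair in ccep_graph.records:
            zmap = ccep_graph.z_lookup(pair)
            f_ccep_z = (
                sum(
                    z * activation.hg_pca[c]
                    for c, z in zmap.items()
                    if analyzable[c]
                )
                / n_electrodes
            )
            f_ccep_edges = (
                ccep_graph.edge_count[pair]
                * activation.hg_pca[analyzable].sum()
                / n_electrodes
            )
        rows.append(
            dict(
                pair=pair,
                f_alltime=f_alltime,
                f_pca=f_pca,
                f_centrality=f_cent,
                f_ccep_z=f_ccep_z,
                f_ccep_edges=f_ccep_edges,
                esm_label=int(esm_labels[pair]),
            )
        )
    return pd.DataFrame(rows)
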
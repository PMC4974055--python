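"""Pairwise Pearson correlation, scrambled-trace null cut-off, functional graph.

The functional network is defined by thresholding the cells × cells Pearson
correlation matrix at a data-driven cut-off: each trace is independently
circularly shifted in time (which preserves its marginal distribution and
autocorrelation while destroying cross-cell alignment), the 99th percentile
of the resulting off-diagonal correlation distribution is recorded, and the
cut-off is the mean of that percentile over scramble realizations.  Cell
pairs at or above the cut-off are "correlating pairs" and become graph edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .traces import EventSeries, NormalizedTraceSet


@dataclass
class CorrelationResult:
    """Pairwise Pearson matrix plus the scramble-derived cut-off.

    ``matrix`` is symmetric with unit diagonal; entries involving invalid
    (constant or flagged) cells are NaN.  ``cutoff`` is None until
    :func:`scrambled_cutoff` has been applied.
    """

    matrix: np.ndarray
    valid: np.ndarray
    cutoff: float | None = None
    n_scrambles: int = 0
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path, roi_ids=None) -> None:
        ids = roi_ids or [f"cell_{i:03d}" for i in range(self.n_cells)]
        pd.DataFrame(self.matrix, index=ids, columns=ids).to_csv(
            path, float_format="%.10g")


def _valid_rows(norm: NormalizedTraceSet) -> np.ndarray:
    x = norm.values
    finite = np.all(np.isfinite(x), axis=1)
    nonconst = np.ptp(x, axis=1) > 0
    flagged = norm.invalid if norm.invalid is not None else np.zeros(x.shape[0], bool)
    return finite & nonconst & ~flagged


def correlation_matrix(norm: NormalizedTraceSet) -> CorrelationResult:
    """Pearson r for every unordered pair of valid cells.

    Constant or invalid traces get NaN rows/columns (with a warning) and are
    excluded from all downstream pair counts.
    """
    if norm.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if norm.n_frames < 3:
        raise ValueError("need at least 3 frames")
    valid = _valid_rows(norm)
    if not valid.all():
        bad = [norm.roi_ids[i] for i in np.flatnonzero(~valid)]
        warnings.warn(f"constant or invalid traces excluded from correlation: {bad}")
    mat = np.full((norm.n_cells, norm.n_cells), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size >= 2:
        sub = np.corrcoef(norm.values[idx])
        mat[np.ix_(idx, idx)] = sub
    mat[idx, idx] = 1.0
    return CorrelationResult(matrix=mat, valid=valid)


def _circular_shift_rows(x: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    cols = (np.arange(n)[None, :] - shifts[:, None]) % n
    return np.take_along_axis(x, cols, axis=1)


def scrambled_cutoff(norm: NormalizedTraceSet, n_scrambles: int = 100,
                     seed: int = 0) -> float:
    """Correlation cut-off from circularly time-shifted surrogate traces.

    For each realization every valid trace is independently shifted by a
    uniform random offset in [1, n_frames−1] with wrap-around; the 99th
    percentile (linear interpolation) of the pooled off-diagonal
    upper-triangle correlations is recorded.  The cut-off is the mean of
    these percentiles across realizations.  Deterministic per seed.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be at least 1")
    valid = _valid_rows(norm)
    x = norm.values[valid]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 valid cells for a percentile cut-off")
    rng = np.random.default_rng(seed)
    n_frames = x.shape[1]
    iu = np.triu_indices(x.shape[0], k=1)
    percs = np.empty(n_scrambles)
    for s in range(n_scrambles):
        shifts = rng.integers(1, n_frames, size=x.shape[0])
        c = np.corrcoef(_circular_shift_rows(x, shifts))
        percs[s] = np.percentile(c[iu], 99)
    return float(percs.mean())


def event_train_correlation(events: EventSeries, frame_interval: float,
                            n_frames: int, smooth_sd: float = 2.0) -> CorrelationResult:
    """Pearson correlation of smoothed binary event trains.

    Alternative to continuous-trace correlation: each cell's events are
    binned at the frame interval and convolved with a Gaussian of SD
    ``smooth_sd`` seconds, so coincident transients correlate regardless of
    their amplitudes.  Cells without events are marked invalid.
    """
    from scipy import ndimage

    trains = np.zeros((events.n_cells, n_frames))
    for i, t in enumerate(events.times):
        idx = np.clip(np.round(np.asarray(t) / frame_interval).astype(int),
                      0, n_frames - 1)
        np.add.at(trains[i], idx, 1.0)
    trains = ndimage.gaussian_filter1d(trains, smooth_sd / frame_interval,
                                       axis=1, mode="constant")
    norm = NormalizedTraceSet(values=trains, frame_interval=frame_interval,
                              roi_ids=list(events.roi_ids))
    return correlation_matrix(norm)


def attach_cutoff(corr: CorrelationResult, cutoff: float,
                  n_scrambles: int, seed: int) -> CorrelationResult:
    corr.cutoff = float(cutoff)
    corr.n_scrambles = int(n_scrambles)
    corr.seed = seed
    return corr


def build_graph(corr: CorrelationResult, events: EventSeries,
                centroids: np.ndarray | None = None) -> nx.Graph:
    """Threshold the correlation matrix into the functional graph.

    Nodes are active valid cells; an edge joins a pair whose Pearson r is at
    or above the cut-off (signed r — anti-correlated pairs are not edges).
    Edge weights retain r for visualization.
    """
    if corr.cutoff is None:
        raise ValueError("attach a scrambled cut-off before building the graph")
    active = events.active & corr.valid
    g = nx.Graph(cutoff=corr.cutoff)
    for i in np.flatnonzero(active):
        attrs = {"roi_id": events.roi_ids[i]}
        if centroids is not None:
            attrs["centroid"] = tuple(map(float, centroids[i]))
        g.add_node(int(i), **attrs)
    idx = np.flatnonzero(active)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            r = corr.matrix[idx[a], idx[b]]
            if np.isfinite(r) and r >= corr.cutoff:
                g.add_edge(int(idx[a]), int(idx[b]), weight=float(r))
    return g


def edges_to_csv(g: nx.Graph, path, roi_ids=None) -> None:
    rows = [((roi_ids[u] if roi_ids else u), (roi_ids[v] if roi_ids else v),
             d["weight"]) for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["cell_a", "cell_b", "r"]).to_csv(
        path, index=False, float_format="%.10g")


def write_graphml(g: nx.Graph, path) -> None:
    h = g.copy()
    for _, d in h.nodes(data=True):
        if "centroid" in d:
            d["centroid"] = ",".join(f"{c:g}" for c in d["centroid"])
    nx.write_graphml(h, path)


def plot_network_overlay(g: nx.Graph, sd_image: np.ndarray, path) -> None:
    """Edges drawn over the SD image, colored by correlation strength."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(sd_image, cmap="gray")
    cmap = plt.get_cmap("plasma")
    for u, v, d in g.edges(data=True):
        cu = g.nodes[u].get("centroid")
        cv = g.nodes[v].get("centroid")
        if cu is None or cv is None:
            continue
        ax.plot([cu[1], cv[1]], [cu[0], cv[0]],
                color=cmap(np.clip(d["weight"], 0, 1)), lw=1)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 1))
    fig.colorbar(sm, ax=ax, label="Pearson r")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
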
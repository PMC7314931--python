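"""Weighted network construction and the four dynamic topology metrics.

Each window's edge vector is thresholded edgewise (two-tailed correlation
test, Bonferroni over the E edges, positive correlations only) into a
symmetric weighted adjacency matrix with weights in [0, 1]. On each such
network the four weighted metrics of Rubinov-Sporns-style graph analysis
are computed:

* ``cw`` — weighted clustering coefficient, geometric-mean (Onnela)
  triangle intensity with weights normalized by the network maximum and a
  binary-degree denominator; mean over all nodes.
* ``lw`` — characteristic path length, mean shortest-path distance over
  finite ordered pairs with edge length 1/weight; the fraction of
  disconnected (infinite) pairs is reported alongside.
* ``eglob`` — global efficiency, mean inverse shortest-path distance
  (1/inf = 0).
* ``eloc`` — local efficiency, mean over nodes of the global efficiency of
  each node's neighbor-induced subgraph (original weights); nodes with
  fewer than two neighbors contribute 0.

Per-window metrics are then averaged within each dFC state per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger("dfcnet")

__all__ = [
    "critical_r",
    "threshold_edges",
    "clustering_coefficient_w",
    "shortest_distances",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "window_topology",
    "state_topology",
    "WindowGraphMetrics",
    "TopologyMetrics",
]


@dataclass(frozen=True)
class TopologyMetrics:
    cw: float
    lw: float
    eglob: float
    eloc: float
    inf_pair_fraction: float = 0.0


def critical_r(window_length: int, alpha: float, n_edges: int) -> float:
    """Smallest |r| significant at the Bonferroni-corrected two-tailed level
    for a window of ``window_length`` samples (df = L - 2)."""
    df = window_length - 2
    t_crit = sstats.t.ppf(1.0 - (alpha / n_edges) / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def threshold_edges(
    edge_vector: np.ndarray,
    window_length: int,
    alpha: float = 0.05,
    n_edges: int | None = None,
) -> np.ndarray:
    """Edgewise significance thresholding of one window's correlations.

    An edge is kept iff its two-tailed p-value (t = r sqrt((L-2)/(1-r^2)),
    df = L-2) passes Bonferroni over ``n_edges`` AND r > 0; kept weights are
    the raw correlations, removed edges are 0. Returns the N x N symmetric
    adjacency matrix with zero diagonal.
    """
    edge_vector = np.asarray(edge_vector, dtype=float)
    if window_length < 4:
        raise ValueError("window_length must be >= 4")
    e = edge_vector.shape[-1]
    if n_edges is None:
        n_edges = e
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    rc = critical_r(window_length, alpha, n_edges)
    kept = np.where((edge_vector > 0) & (np.abs(edge_vector) >= rc), edge_vector, 0.0)
    kept = np.minimum(kept, 1.0)
    adj = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    adj[iu, ju] = kept
    adj[ju, iu] = kept
    return adj


def _check_network(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("network must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("network must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if np.abs(np.diag(w)).max(initial=0.0) > 0:
        raise ValueError("diagonal must be zero")
    return w


def clustering_coefficient_w(network: np.ndarray) -> float:
    """Weighted clustering coefficient (geometric-mean triangles).

    Weights are normalized by the maximum weight; node triangle intensity
    t_i = 1/2 sum_{j,h} (w_ij w_ih w_jh)^(1/3); C_i = 2 t_i / (k_i (k_i-1))
    with binary degree k_i; nodes with k_i < 2 contribute 0; returns the
    mean over all N nodes. An edgeless network has cw = 0.
    """
    w = _check_network(network)
    wmax = w.max()
    if wmax == 0:
        return 0.0
    wn = (w / wmax) ** (1.0 / 3.0)
    tri = np.diag(wn @ wn @ wn) / 2.0
    k = (w > 0).sum(axis=0)
    denom = k * (k - 1)
    c = np.where(denom > 0, 2.0 * tri / np.maximum(denom, 1), 0.0)
    return float(c.mean())


def shortest_distances(network: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length = 1/weight.

    Unreachable pairs are +inf; the diagonal is 0. Vectorized
    Floyd-Warshall (cross-checked against Dijkstra in the test suite).
    """
    w = _check_network(network)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        d = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def characteristic_path_length(distances: np.ndarray) -> tuple[float, float]:
    """(Lw, infinite-pair fraction) over ordered pairs i != j.

    Lw averages finite distances only; if every pair is disconnected Lw is
    NaN (undefined) with infinite fraction 1.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    inf_frac = float(1.0 - finite.mean()) if vals.size else 1.0
    if not finite.any():
        return float("nan"), 1.0
    return float(vals[finite].mean()), inf_frac


def global_efficiency(distances: np.ndarray) -> float:
    """Mean of 1/d over ordered pairs i != j, with 1/inf = 0."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(network: np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency.

    The subgraph induced on node i's neighbors keeps the original weights;
    nodes with < 2 neighbors contribute 0.
    """
    w = _check_network(network)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        total += global_efficiency(shortest_distances(sub))
    return total / n


def window_metrics(network: np.ndarray) -> TopologyMetrics:
    """All four metrics for one window network."""
    d = shortest_distances(network)
    lw, inf_frac = characteristic_path_length(d)
    return TopologyMetrics(
        cw=clustering_coefficient_w(network),
        lw=lw,
        eglob=global_efficiency(d),
        eloc=local_efficiency(network),
        inf_pair_fraction=inf_frac,
    )


def window_topology(
    window_corrs: np.ndarray,
    window_length: int,
    alpha: float = 0.05,
    n_edges: int | None = None,
) -> pd.DataFrame:
    """Per-window metrics for one subject's (W, E) windowed correlations."""
    window_corrs = np.asarray(window_corrs, dtype=float)
    rows = []
    for wv in window_corrs:
        net = threshold_edges(wv, window_length, alpha=alpha, n_edges=n_edges)
        rows.append(window_metrics(net))
    return pd.DataFrame(
        {
            "cw": [m.cw for m in rows],
            "lw": [m.lw for m in rows],
            "eglob": [m.eglob for m in rows],
            "eloc": [m.eloc for m in rows],
            "inf_pair_fraction": [m.inf_pair_fraction for m in rows],
        }
    )


def state_topology(
    per_window: pd.DataFrame | list[pd.DataFrame],
    labels: np.ndarray,
    subject_ids: list[str] | None = None,
    k: int | None = None,
) -> pd.DataFrame:
    """Average per-window metrics within each state per subject.

    ``per_window`` is one DataFrame per subject from :func:`window_topology`.
    Windows with undefined (NaN) Lw are excluded from the Lw mean (logged);
    zero-occupancy states are omitted.
    """
    if isinstance(per_window, pd.DataFrame):
        per_window = [per_window]
    labels = np.asarray(labels, dtype=int)
    if k is None:
        k = int(labels.max())
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(len(per_window))]
    recs = []
    n_dropped = 0
    for sid, df in zip(subject_ids, per_window):
        if len(df) != len(labels):
            raise ValueError("per-window table length must equal labels length")
        for state in range(1, k + 1):
            m = labels == state
            if not m.any():
                continue
            sub = df.loc[m]
            lw_vals = sub["lw"].dropna()
            n_dropped += int(sub["lw"].isna().sum())
            recs.append(
                {
                    "subject": sid,
                    "state": state,
                    "cw": sub["cw"].mean(),
                    "lw": lw_vals.mean() if len(lw_vals) else np.nan,
                    "eglob": sub["eglob"].mean(),
                    "eloc": sub["eloc"].mean(),
                    "inf_pair_fraction": sub["inf_pair_fraction"].mean(),
                }
            )
    if n_dropped:
        logger.info("excluded %d windows with undefined Lw from state means", n_dropped)
    return pd.DataFrame(recs)


class WindowGraphMetrics(BaseEstimator, TransformerMixin):
    """Transformer from windowed correlations to per-window graph metrics.

    Parameters
    ----------
    window_length_tr : int, default 35
        Window length used for the edgewise significance threshold.
    edge_alpha : float, default 0.05
        Family-wise alpha, Bonferroni-corrected over the E edges per window.
    """

    def __init__(self, window_length_tr: int = 35, edge_alpha: float = 0.05):
        self.window_length_tr = window_length_tr
        self.edge_alpha = edge_alpha

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        """X: (W, E) array or list of them; returns DataFrame or list."""
        if isinstance(X, list):
            return [window_topology(x, self.window_length_tr, self.edge_alpha) for x in X]
        return window_topology(X, self.window_length_tr, self.edge_alpha)
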
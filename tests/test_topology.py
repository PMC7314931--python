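"""Weighted graph metrics against hand values and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sstats
from scipy.sparse.csgraph import dijkstra

from dfcnet.topology import (
    characteristic_path_length,
    clustering_coefficient_w,
    critical_r,
    global_efficiency,
    local_efficiency,
    shortest_distances,
    threshold_edges,
    window_metrics,
    state_topology,
    window_topology,
)

# ----------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ----------------------------------------------------------------------


def _cw_oracle(w):
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (w[i, j] / wmax * w[i, h] / wmax * w[j, h] / wmax) ** (1 / 3)
        total += (t / 2.0) * 2.0 / (k * (k - 1))
    return total / n


def _dist_oracle(w):
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return dijkstra(np.where(np.isfinite(lengths), lengths, 0.0), directed=False,
                    unweighted=False)


def _lw_oracle(d):
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return np.mean(vals) if vals else float("nan")


def _eglob_oracle(d):
    n = d.shape[0]
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i in range(n) for j in range(n) if i != j]
    return np.mean(vals) if vals else 0.0


def _eloc_oracle(w):
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        total += _eglob_oracle(_dist_oracle(w[np.ix_(nb, nb)]))
    return total / n


def _random_network(rng, n):
    w = np.triu(rng.uniform(0.1, 1.0, size=(n, n)), k=1)
    w *= rng.random((n, n)) < 0.6
    w = w + w.T
    return w


# ----------------------------------------------------------------------
# edge thresholding
# ----------------------------------------------------------------------


class TestThresholdEdges:
    def test_zero_correlation_removed(self):
        net = threshold_edges(np.zeros(3), window_length=35)
        assert net.sum() == 0

    def test_critical_r_boundary(self):
        """Edges just above the Bonferroni critical r survive; just below
        are removed (independent t-quantile oracle)."""
        L, alpha, m = 35, 0.05, 136
        t_crit = sstats.t.ppf(1 - (alpha / m) / 2, L - 2)
        rc = t_crit / np.sqrt(L - 2 + t_crit**2)
        ev = np.array([rc * 1.001, rc * 0.999, -rc * 1.5])
        net = threshold_edges(ev, L, alpha=alpha, n_edges=m)
        assert net[0, 1] == pytest.approx(rc * 1.001)
        assert net[0, 2] == 0.0  # below threshold
        assert net[1, 2] == 0.0  # negative r excluded

    def test_all_strong_edges_give_complete_graph(self):
        ev = np.full(6, 0.99)
        net = threshold_edges(ev, 35)
        off = ~np.eye(4, dtype=bool)
        assert (net[off] > 0).all()

    def test_negative_edges_always_excluded(self):
        ev = np.array([-0.99, 0.99, 0.99])
        net = threshold_edges(ev, 35)
        assert net[0, 1] == 0.0 and net[0, 2] > 0 and net[1, 2] > 0


# ----------------------------------------------------------------------
# hand-computed values
# ----------------------------------------------------------------------


def _net(n, edges):
    w = np.zeros((n, n))
    for i, j, wt in edges:
        w[i, j] = w[j, i] = wt
    return w


class TestHandValues:
    def test_complete_unit_triangle(self):
        tri = _net(3, [(0, 1, 1), (0, 2, 1), (1, 2, 1)])
        d = shortest_distances(tri)
        assert clustering_coefficient_w(tri) == pytest.approx(1.0)
        assert characteristic_path_length(d)[0] == pytest.approx(1.0)
        assert global_efficiency(d) == pytest.approx(1.0)
        assert local_efficiency(tri) == pytest.approx(1.0)

    def test_three_node_unit_path(self):
        path = _net(3, [(0, 1, 1), (1, 2, 1)])
        d = shortest_distances(path)
        assert clustering_coefficient_w(path) == 0.0
        assert characteristic_path_length(d)[0] == pytest.approx(4.0 / 3.0)
        assert global_efficiency(d) == pytest.approx(5.0 / 6.0)
        assert local_efficiency(path) == 0.0

    def test_half_weight_edge_doubles_length(self):
        net = _net(2, [(0, 1, 0.5)])
        d = shortest_distances(net)
        assert d[0, 1] == pytest.approx(2.0)

    def test_unit_path_distance_adds(self):
        net = _net(3, [(0, 1, 1), (1, 2, 1)])
        assert shortest_distances(net)[0, 2] == pytest.approx(2.0)

    def test_disconnected_pairs(self):
        net = _net(4, [(0, 1, 1), (2, 3, 1)])
        d = shortest_distances(net)
        lw, inf_frac = characteristic_path_length(d)
        assert lw == pytest.approx(1.0)
        assert inf_frac == pytest.approx(2.0 / 3.0)

    def test_edgeless_graph(self):
        net = np.zeros((4, 4))
        d = shortest_distances(net)
        assert clustering_coefficient_w(net) == 0.0
        assert global_efficiency(d) == 0.0
        lw, inf_frac = characteristic_path_length(d)
        assert np.isnan(lw) and inf_frac == 1.0


# ----------------------------------------------------------------------
# oracle equivalence
# ----------------------------------------------------------------------


class TestOracleEquivalence:
    def test_exhaustive_small_graphs(self):
        """All binary topologies on 4 and 5 nodes x 3 weight draws agree
        with brute-force metric oracles to 1e-12."""
        rng = np.random.default_rng(99)
        for n in (4, 5):
            iu = list(zip(*np.triu_indices(n, k=1)))
            for mask_bits in range(2 ** len(iu)):
                weight_draws = [np.ones(len(iu))] + [
                    rng.uniform(0.1, 1.0, len(iu)) for _ in range(2)
                ]
                for wts in weight_draws:
                    w = np.zeros((n, n))
                    for b, (i, j) in enumerate(iu):
                        if mask_bits >> b & 1:
                            w[i, j] = w[j, i] = wts[b]
                    d = shortest_distances(w)
                    assert np.allclose(d, _dist_oracle(w), atol=1e-12, equal_nan=True)
                    assert clustering_coefficient_w(w) == pytest.approx(_cw_oracle(w), abs=1e-12)
                    assert global_efficiency(d) == pytest.approx(_eglob_oracle(d), abs=1e-12)
                    assert local_efficiency(w) == pytest.approx(_eloc_oracle(w), abs=1e-12)
                    lw = characteristic_path_length(d)[0]
                    lw_o = _lw_oracle(d)
                    if np.isnan(lw_o):
                        assert np.isnan(lw)
                    else:
                        assert lw == pytest.approx(lw_o, abs=1e-12)

    def test_random_medium_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = 6 if trial % 2 == 0 else 7
            w = _random_network(rng, n)
            d = shortest_distances(w)
            assert np.allclose(d, _dist_oracle(w), atol=1e-12)
            assert clustering_coefficient_w(w) == pytest.approx(_cw_oracle(w), abs=1e-12)
            assert local_efficiency(w) == pytest.approx(_eloc_oracle(w), abs=1e-12)
            assert global_efficiency(d) == pytest.approx(_eglob_oracle(d), abs=1e-12)


# ----------------------------------------------------------------------
# structural properties
# ----------------------------------------------------------------------


class TestProperties:
    def test_eglob_at_least_inverse_lw(self, rng):
        """Jensen: mean of inverses >= inverse of mean over finite pairs."""
        for _ in range(20):
            w = _random_network(rng, 6)
            d = shortest_distances(w)
            lw, _ = characteristic_path_length(d)
            finite = np.isfinite(d) & ~np.eye(6, dtype=bool)
            if not finite.any() or np.isnan(lw):
                continue
            mean_inv = (1.0 / d[finite]).mean()
            assert mean_inv >= 1.0 / lw - 1e-12

    def test_adding_edge_never_hurts(self, rng):
        for _ in range(10):
            w = _random_network(rng, 6)
            d = shortest_distances(w)
            zero = np.argwhere(np.triu(w == 0, k=1))
            if len(zero) == 0:
                continue
            i, j = zero[0]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 0.5
            d2 = shortest_distances(w2)
            assert global_efficiency(d2) >= global_efficiency(d) - 1e-12
            both = np.isfinite(d)
            assert (d2[both] <= d[both] + 1e-12).all()

    def test_weight_scaling(self, rng):
        """cw invariant under global weight scaling; eglob scales linearly."""
        for _ in range(10):
            w = _random_network(rng, 6)
            c = 0.37
            assert clustering_coefficient_w(c * w) == pytest.approx(
                clustering_coefficient_w(w), abs=1e-12
            )
            e1 = global_efficiency(shortest_distances(w))
            e2 = global_efficiency(shortest_distances(c * w))
            assert e2 == pytest.approx(c * e1, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            shortest_distances(np.array([[0.0, 1.0], [0.5, 0.0]]))


# ----------------------------------------------------------------------
# per-window / per-state aggregation
# ----------------------------------------------------------------------


class TestStateAggregation:
    def test_identical_windows_give_window_value(self, rng):
        ev = rng.uniform(0.5, 0.9, size=6)
        wc = np.tile(ev, (8, 1))
        df = window_topology(wc, window_length=35)
        labels = np.r_[np.ones(4, int), np.full(4, 2, int)]
        out = state_topology(df, labels)
        ref = window_metrics(threshold_edges(ev, 35))
        for state in (1, 2):
            row = out[out.state == state].iloc[0]
            assert row.cw == pytest.approx(ref.cw)
            assert row.eglob == pytest.approx(ref.eglob)

    def test_zero_occupancy_state_missing(self, rng):
        wc = rng.uniform(0, 1, size=(5, 6))
        df = window_topology(wc, 35)
        out = state_topology(df, np.ones(5, int), k=3)
        assert set(out.state) == {1}

    def test_denser_state_has_higher_efficiency(self):
        """A strongly intra-connected state yields higher mean Eglob than a
        weakly connected one across seeds."""
        from dfcnet.synth import StateModel, simulate_subject
        from dfcnet.dfc import WindowSpec, window_correlations

        n = 8
        dense = 0.75 * np.ones((n, n)) + 0.25 * np.eye(n)
        sparse = np.eye(n) + 0.1 - 0.1 * np.eye(n)
        model = StateModel(np.stack([dense, sparse]), np.eye(2), mean_dwell=100)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            labels = np.r_[np.ones(70, int), np.full(70, 2, int)]
            s = simulate_subject(model, labels, noise_sd=0.5, rng_seed=seed)
            wc = window_correlations(s, WindowSpec(35, 1))
            df = window_topology(wc, 35)
            pure1 = df.iloc[:36]["eglob"].mean()   # windows fully in state 1
            pure2 = df.iloc[70:]["eglob"].mean()
            wins += pure1 > pure2
        assert wins >= 0.9 * n_seeds

    def test_weights_bounded_after_threshold(self, rng):
        ev = rng.uniform(-1, 1, size=136)
        net = threshold_edges(ev, 35)
        assert net.min() >= 0.0 and net.max() <= 1.0
        assert np.allclose(np.diag(net), 0.0)


class TestCriticalR:
    def test_matches_p_value_computation(self):
        rc = critical_r(35, 0.05, 136)
        t = rc * np.sqrt((35 - 2) / (1 - rc**2))
        p = 2 * sstats.t.sf(t, 33)
        assert p == pytest.approx(0.05 / 136, rel=1e-9)
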
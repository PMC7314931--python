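"""Seed-based node identification: spheres, correlation maps, Fisher z,
one-sample t, FWE thresholding, clusters, node tables, phantom recovery."""

import numpy as np
import pandas as pd
import pytest

from dfcnet.nodes import (
    DEFAULT_SEEDS,
    SeedNodeIdentifier,
    SeedSpec,
    StatMap,
    build_node_table,
    extract_clusters,
    extract_node_series,
    fisher_z,
    fwe_voxel_threshold,
    onesample_t_map,
    seed_fc_map,
    sphere_voxels,
)
from dfcnet.synth import simulate_phantom_cohort, simulate_volume_phantom

AFF3 = np.diag([3.0, 3.0, 3.0, 1.0])


def _small_node_table():
    return pd.DataFrame(
        {
            "seed": ["S1", "S1"],
            "node": ["A", "B"],
            "x": [15.0, -12.0],
            "y": [18.0, -9.0],
            "z": [9.0, 12.0],
            "radius_mm": [3.0, 3.0],
        }
    )


class TestSphereVoxels:
    def test_three_mm_radius_on_three_mm_grid_is_seven_voxels(self):
        """Lattice points within 3 mm of a voxel center: the center plus its
        six face neighbors."""
        vox = sphere_voxels((15.0, 15.0, 15.0), 3.0, AFF3, (11, 11, 11))
        assert len(vox) == 7
        center = np.array([5, 5, 5])
        offsets = {tuple(v - center) for v in vox}
        expected = {(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)}
        assert offsets == expected

    def test_tiny_radius_single_voxel(self):
        vox = sphere_voxels((15.0, 15.0, 15.0), 0.1, AFF3, (11, 11, 11))
        assert len(vox) == 1

    def test_center_outside_grid_raises(self):
        with pytest.raises(ValueError, match="outside"):
            sphere_voxels((200.0, 0.0, 0.0), 3.0, AFF3, (11, 11, 11))


class TestSeedFCMap:
    def test_identical_series_r_one(self, rng):
        data = np.zeros((7, 7, 7, 30))
        sig = rng.standard_normal(30)
        data[...] = sig  # every voxel identical to seed mean
        m = seed_fc_map(data, AFF3, SeedSpec("s", (9.0, 9.0, 9.0)))
        assert m.values[0, 0, 0] == pytest.approx(1.0)

    def test_negated_series_r_minus_one(self, rng):
        data = np.zeros((7, 7, 7, 30))
        sig = rng.standard_normal(30)
        data[...] = sig
        data[0, 0, 0] = -sig
        m = seed_fc_map(data, AFF3, SeedSpec("s", (9.0, 9.0, 9.0)))
        assert m.values[0, 0, 0] == pytest.approx(-1.0)

    def test_phantom_coupling_matches_attenuation_theory(self):
        """Mean r over planted voxels matches the closed-form value from
        signal and noise variances."""
        nt = _small_node_table()
        coupling, noise = 0.8, 1.0
        ph = simulate_volume_phantom(
            nt, grid_shape=(22, 22, 16), seed_specs=(SeedSpec("S1", (0.0, 0.0, 0.0)),),
            rng_seed=3, n_timepoints=3000, cluster_voxels=40, coupling=coupling,
            noise_sd=noise,
        )
        m = seed_fc_map(ph.data, ph.affine, SeedSpec("S1", (0.0, 0.0, 0.0)))
        # seed mean = s + noise/sqrt(7); voxel = c*s + noise
        var_seed = 1 + noise**2 / 7
        var_vox = coupling**2 + noise**2
        expected = coupling / np.sqrt(var_seed * var_vox)
        inv = np.linalg.inv(ph.affine)
        center = (inv[:3, :3] @ np.array([15.0, 18.0, 9.0]) + inv[:3, 3]).round().astype(int)
        got = m.values[tuple(center)]
        assert got == pytest.approx(expected, abs=0.1)

    def test_zero_variance_seed_errors(self):
        data = np.zeros((7, 7, 7, 10))
        with pytest.raises(ValueError, match="zero variance"):
            seed_fc_map(data, AFF3, SeedSpec("s", (9.0, 9.0, 9.0)))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        m = StatMap(np.zeros((2, 2, 2)), "r", AFF3)
        assert np.all(fisher_z(m).values == 0.0)

    def test_closed_form_half(self):
        m = StatMap(np.full((1, 1, 1), 0.5), "r", AFF3)
        assert fisher_z(m).values[0, 0, 0] == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_odd_symmetry_and_inverse(self):
        r = np.linspace(-0.95, 0.95, 39).reshape(1, 1, -1)
        z_pos = fisher_z(StatMap(r, "r", AFF3)).values
        z_neg = fisher_z(StatMap(-r, "r", AFF3)).values
        assert np.allclose(z_pos, -z_neg, atol=1e-12)
        assert np.allclose(np.tanh(z_pos), r, atol=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(-0.99, 0.99, 100).reshape(1, 1, -1)
        z = fisher_z(StatMap(r, "r", AFF3)).values.ravel()
        assert (np.diff(z) > 0).all()


class TestOneSampleT:
    def test_all_zero_maps_give_zero_t(self):
        maps = [StatMap(np.zeros((3, 3, 3)), "z", AFF3) for _ in range(5)]
        t = onesample_t_map(maps)
        assert np.all(t.values == 0.0) and t.df == 4

    def test_hand_computed_two_subjects(self):
        a = StatMap(np.full((1, 1, 1), 1.0), "z", AFF3)
        b = StatMap(np.full((1, 1, 1), 3.0), "z", AFF3)
        t = onesample_t_map([a, b])
        assert t.values[0, 0, 0] == pytest.approx(2.0)

    def test_constant_nonzero_gives_infinite_t(self):
        maps = [StatMap(np.full((1, 1, 1), 0.7), "z", AFF3) for _ in range(4)]
        t = onesample_t_map(maps)
        assert np.isposinf(t.values[0, 0, 0])

    def test_null_exceedance_rate(self):
        """P(|t| > Bonferroni threshold) under the null is ~alpha/n_voxels."""
        rng = np.random.default_rng(0)
        n_vox, n_sub, alpha = 4000, 21, 0.05
        maps = [StatMap(rng.standard_normal((1, 1, n_vox)), "z", AFF3) for _ in range(n_sub)]
        t = onesample_t_map(maps)
        keep = fwe_voxel_threshold(t, alpha=alpha, mask=np.ones((1, 1, n_vox)))
        # expected false positives ~ alpha; allow generous Poisson slack
        assert keep.sum() <= 5

    def test_grid_mismatch_raises(self):
        a = StatMap(np.zeros((2, 2, 2)), "z", AFF3)
        b = StatMap(np.zeros((3, 3, 3)), "z", AFF3)
        with pytest.raises(ValueError):
            onesample_t_map([a, b])


class TestFWEThreshold:
    def test_threshold_monotone_in_alpha(self, rng):
        t = StatMap(rng.standard_normal((6, 6, 6)) * 3, "t", AFF3, df=20)
        keep_strict = fwe_voxel_threshold(t, alpha=0.001, mask=np.ones((6, 6, 6)))
        keep_loose = fwe_voxel_threshold(t, alpha=0.05, mask=np.ones((6, 6, 6)))
        assert not (keep_strict & ~keep_loose).any()

    def test_infinite_t_always_kept(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = np.inf
        keep = fwe_voxel_threshold(StatMap(vals, "t", AFF3, df=5), alpha=0.01,
                                   mask=np.ones((2, 2, 2)))
        assert keep[0, 0, 0] and keep.sum() == 1

    def test_mask_restricts_voxels(self, rng):
        t = StatMap(np.full((4, 4, 4), 50.0), "t", AFF3, df=20)
        mask = np.zeros((4, 4, 4))
        mask[:2] = 0.95
        keep = fwe_voxel_threshold(t, alpha=0.01, mask=mask)
        assert keep[:2].all() and not keep[2:].any()

    def test_empty_mask_raises(self, rng):
        t = StatMap(np.zeros((3, 3, 3)), "t", AFF3, df=10)
        with pytest.raises(ValueError):
            fwe_voxel_threshold(t, mask=np.zeros((3, 3, 3)))


class TestClusters:
    def _tmap(self, shape, value=10.0):
        return StatMap(np.full(shape, value), "t", AFF3, df=20)

    def test_single_blob_recovered_with_size(self):
        binary = np.zeros((10, 10, 10), bool)
        binary[2:6, 2:6, 2:6] = True  # 64 voxels
        t = self._tmap((10, 10, 10))
        t.values[3, 3, 3] = 99.0
        clusters = extract_clusters(binary, t, min_size=50)
        assert len(clusters) == 1
        assert clusters[0].size == 64
        assert clusters[0].peak_mni == (9.0, 9.0, 9.0)

    def test_blob_below_min_size_excluded(self):
        binary = np.zeros((10, 10, 10), bool)
        binary[0, 0, :7] = True
        assert extract_clusters(binary, self._tmap((10, 10, 10)), min_size=8) == []

    def test_corner_touching_blobs_split_by_connectivity(self):
        binary = np.zeros((6, 6, 6), bool)
        binary[0:2, 0:2, 0:2] = True
        binary[2:4, 2:4, 2:4] = True  # touches only at a corner
        t = self._tmap((6, 6, 6))
        six = extract_clusters(binary, t, min_size=1, connectivity=6)
        twentysix = extract_clusters(binary, t, min_size=1, connectivity=26)
        assert len(six) == 2 and len(twentysix) == 1

    def test_clusters_disjoint_and_cover(self, rng):
        binary = rng.random((8, 8, 8)) < 0.3
        t = StatMap(rng.standard_normal((8, 8, 8)), "t", AFF3, df=10)
        clusters = extract_clusters(binary, t, min_size=1)
        total = sum(c.size for c in clusters)
        assert total == int(binary.sum())
        seen = set()
        for c in clusters:
            for ijk in map(tuple, c.voxel_indices):
                assert ijk not in seen
                seen.add(ijk)


class TestNodeTableAndRecovery:
    def test_one_cluster_one_node_at_peak(self):
        binary = np.zeros((8, 8, 8), bool)
        binary[1:5, 1:5, 1:5] = True
        t = StatMap(np.ones((8, 8, 8)), "t", AFF3, df=10)
        t.values[2, 3, 4] = 9.0
        clusters = extract_clusters(binary, t, min_size=10)
        table = build_node_table({"Broca": clusters})
        assert len(table) == 1
        assert tuple(table.iloc[0][["x", "y", "z"]]) == (6.0, 9.0, 12.0)

    def test_phantom_end_to_end_recovery(self):
        """Planted 60-voxel clusters are recovered as >= 50-voxel clusters
        with peaks inside the planted blobs."""
        nt = _small_node_table()
        seeds = (SeedSpec("S1", (0.0, 0.0, 0.0)),)
        ph = simulate_phantom_cohort(
            nt, n_subjects=12, rng_seed=5, seed_specs=seeds,
            grid_shape=(22, 22, 16), n_timepoints=60, cluster_voxels=60, coupling=0.8,
        )
        ident = SeedNodeIdentifier(seeds=seeds, min_cluster_voxels=50).fit(
            [p.data for p in ph], ph[0].affine, ph[0].gm_mask
        )
        got = ident.nodes_
        assert len(got) >= 2
        for _, planted in nt.iterrows():
            dist = np.sqrt(
                (got.x - planted.x) ** 2 + (got.y - planted.y) ** 2 + (got.z - planted.z) ** 2
            )
            assert dist.min() <= 6.0
        assert all(len(v) == 0 for v in ident.negative_clusters_.values())

    def test_null_phantom_no_clusters(self):
        """With zero coupling nothing should survive FWE + cluster size."""
        nt = _small_node_table()
        seeds = (SeedSpec("S1", (0.0, 0.0, 0.0)),)
        ph = simulate_phantom_cohort(
            nt, n_subjects=8, rng_seed=11, seed_specs=seeds,
            grid_shape=(18, 18, 14), n_timepoints=40, cluster_voxels=40, coupling=0.0,
        )
        with pytest.raises(ValueError, match="no clusters"):
            SeedNodeIdentifier(seeds=seeds, min_cluster_voxels=50).fit(
                [p.data for p in ph], ph[0].affine, ph[0].gm_mask
            )

    def test_extract_node_series_shape(self):
        nt = _small_node_table()
        seeds = (SeedSpec("S1", (0.0, 0.0, 0.0)),)
        ph = simulate_volume_phantom(nt, grid_shape=(22, 22, 16), seed_specs=seeds,
                                     rng_seed=0, n_timepoints=30)
        series = extract_node_series(ph.data, ph.affine, nt)
        assert series.shape == (30, 2)

    def test_default_seeds_are_broca_and_wernicke(self):
        names = {s.name: s.center_mni for s in DEFAULT_SEEDS}
        assert names["Broca"] == (-53.0, 20.0, 15.0)
        assert names["Wernicke"] == (-51.0, -51.0, 30.0)
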
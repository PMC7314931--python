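"""Seed-based identification of language-network nodes from 4-D volumes.

Pipeline per cohort: extract each seed sphere's mean time series, correlate
it with every voxel (Pearson r), Fisher r-to-z transform, one-sample t-test
across subjects, Bonferroni FWE voxel thresholding inside a gray-matter
probability mask (>= 0.9), connected-component cluster extraction with a
minimum size (50 voxels), and one 3-mm-radius node per surviving cluster at
its peak-t voxel. Negative-tail clusters are extracted and reported
separately. Real-data users may bypass this stage entirely by supplying the
packaged node table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats
from sklearn.base import BaseEstimator

logger = logging.getLogger("dfcnet")

__all__ = [
    "SeedSpec",
    "StatMap",
    "Cluster",
    "DEFAULT_SEEDS",
    "sphere_voxels",
    "seed_fc_map",
    "fisher_z",
    "onesample_t_map",
    "fwe_voxel_threshold",
    "extract_clusters",
    "build_node_table",
    "extract_node_series",
    "SeedNodeIdentifier",
]


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed region in MNI millimeters."""

    name: str
    center_mni: tuple[float, float, float]
    radius_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


#: The two canonical language seeds: Broca's and Wernicke's areas.
DEFAULT_SEEDS = (
    SeedSpec("Broca", (-53.0, 20.0, 15.0)),
    SeedSpec("Wernicke", (-51.0, -51.0, 30.0)),
)


@dataclass
class StatMap:
    """A 3-D per-voxel statistic map (r, z, or t) with its affine."""

    values: np.ndarray
    kind: str
    affine: np.ndarray
    df: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("r", "z", "t"):
            raise ValueError("kind must be one of r, z, t")
        if self.kind == "r" and np.nanmax(np.abs(self.values), initial=0) > 1 + 1e-9:
            raise ValueError("r values must lie in [-1, 1]")
        if self.kind == "t" and (self.df is None or self.df < 1):
            raise ValueError("t maps need df >= 1")


@dataclass
class Cluster:
    """A supra-threshold connected component with its peak voxel."""

    voxel_indices: np.ndarray  # (n, 3) int array
    peak_mni: tuple[float, float, float]
    peak_t: float
    sign: str = "positive"

    @property
    def size(self) -> int:
        return len(self.voxel_indices)


def _mni_to_voxel(affine: np.ndarray, xyz) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return inv[:3, :3] @ np.asarray(xyz, float) + inv[:3, 3]


def _voxel_to_mni(affine: np.ndarray, ijk) -> np.ndarray:
    return affine[:3, :3] @ np.asarray(ijk, float) + affine[:3, 3]


def sphere_voxels(
    center_mni,
    radius_mm: float,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxels whose center lies within ``radius_mm`` (inclusive) of the MNI
    center. Returns an (n, 3) index array; empty spheres are an error.

    On a 3-mm grid with a 3-mm radius centered on a voxel center this is the
    7-voxel face-neighborhood.
    """
    center_vox = _mni_to_voxel(affine, center_mni)
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(grid_shape) - 0.5):
        raise ValueError(f"seed center {tuple(center_mni)} maps outside the grid")
    scales = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    lo = np.maximum(np.floor(center_vox - radius_mm / scales - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + radius_mm / scales + 1).astype(int) + 1,
                    np.asarray(grid_shape))
    box = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
    if box.size == 0:
        raise ValueError("seed sphere contains no voxels")
    mm = box @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(mm - np.asarray(center_mni, float), axis=1)
    sel = box[dist <= radius_mm + 1e-9]
    if sel.size == 0:
        raise ValueError("seed sphere contains no voxels")
    return sel


def seed_fc_map(volume4d: np.ndarray, affine: np.ndarray, seed: SeedSpec) -> StatMap:
    """Pearson correlation between the seed-sphere mean series and every
    voxel's series. Zero-variance voxels get r = 0 (counted, logged)."""
    volume4d = np.asarray(volume4d, float)
    if volume4d.ndim != 4 or volume4d.shape[3] < 3:
        raise ValueError("need a 4-D volume with at least 3 time points")
    grid_shape = volume4d.shape[:3]
    vox = sphere_voxels(seed.center_mni, seed.radius_mm, affine, grid_shape)
    seed_series = volume4d[vox[:, 0], vox[:, 1], vox[:, 2]].mean(axis=0)
    s = seed_series - seed_series.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError("seed sphere has zero variance")
    flat = volume4d.reshape(-1, volume4d.shape[3])
    dev = flat - flat.mean(axis=1, keepdims=True)
    denom = np.sqrt((dev**2).sum(axis=1)) * s_norm
    zero = denom == 0
    if zero.any():
        logger.info("%d zero-variance voxels set to r=0", int(zero.sum()))
    r = np.where(zero, 0.0, (dev @ s) / np.where(zero, 1.0, denom))
    r = np.clip(r, -1.0, 1.0).reshape(grid_shape)
    return StatMap(values=r, kind="r", affine=affine)


def fisher_z(map_r: StatMap) -> StatMap:
    """Elementwise Fisher r-to-z: z = atanh(r); |r| = 1 clipped first."""
    if map_r.kind != "r":
        raise ValueError("fisher_z expects an r map")
    r = np.asarray(map_r.values, float)
    clip = np.abs(r) >= 1.0
    if clip.any():
        logger.info("clipping %d voxels with |r| = 1 before Fisher z", int(clip.sum()))
        r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    return StatMap(values=np.arctanh(r), kind="z", affine=map_r.affine)


def onesample_t_map(z_maps: list[StatMap]) -> StatMap:
    """Voxelwise one-sample t across subjects (df = n - 1, sample SD).

    sd = 0 and mean = 0 gives t = 0; sd = 0 with mean != 0 gives signed
    infinity (always supra-threshold downstream).
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = {m.values.shape for m in z_maps}
    if len(shapes) != 1:
        raise ValueError("z maps do not share a grid")
    stack = np.stack([m.values for m in z_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return StatMap(values=t, kind="t", affine=z_maps[0].affine, df=n - 1)


def fwe_voxel_threshold(
    t_map: StatMap,
    alpha: float = 0.01,
    mask: np.ndarray | None = None,
    gm_prob_threshold: float = 0.9,
) -> np.ndarray:
    """Bonferroni voxel-level FWE threshold inside the gray-matter mask.

    A voxel survives iff its gray-matter probability >= ``gm_prob_threshold``
    and its two-tailed t p-value <= alpha / n_mask_voxels. Infinite-t voxels
    always survive. Returns a boolean 3-D map.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t = np.asarray(t_map.values, float)
    if mask is None:
        in_mask = np.ones(t.shape, dtype=bool)
    else:
        in_mask = np.asarray(mask, float) >= gm_prob_threshold
    n_mask = int(in_mask.sum())
    if n_mask == 0:
        raise ValueError("gray-matter mask is empty at this probability threshold")
    with np.errstate(invalid="ignore"):
        p = 2.0 * sstats.t.sf(np.abs(t), t_map.df)
    keep = in_mask & ((p <= alpha / n_mask) | np.isinf(t))
    return keep


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    binary_map: np.ndarray,
    t_map: StatMap,
    min_size: int = 50,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of supra-threshold voxels with size >= min_size.

    Each cluster is annotated with its peak voxel (maximum |t|, reported in
    MNI mm); ties on peak t break toward the smallest linear voxel index.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    labeled, n_comp = ndimage.label(np.asarray(binary_map, bool), _STRUCTURES[connectivity])
    t = np.asarray(t_map.values, float)
    clusters: list[Cluster] = []
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(labeled == lab)
        if len(idx) < min_size:
            continue
        tv = t[idx[:, 0], idx[:, 1], idx[:, 2]]
        abs_tv = np.abs(tv)
        best = int(np.flatnonzero(abs_tv == abs_tv.max())[0])  # argwhere is C-ordered
        peak_ijk = idx[best]
        clusters.append(
            Cluster(
                voxel_indices=idx,
                peak_mni=tuple(_voxel_to_mni(t_map.affine, peak_ijk)),
                peak_t=float(tv[best]),
                sign="positive" if tv[best] >= 0 else "negative",
            )
        )
    clusters.sort(key=lambda c: -abs(c.peak_t))
    return clusters


def build_node_table(clusters_by_seed: dict[str, list[Cluster]], radius_mm: float = 3.0) -> pd.DataFrame:
    """One node per cluster at its peak coordinate, merged across seeds.

    Node names are ``<seed>_<index>``; duplicate peak coordinates across
    seeds are kept with a warning.
    """
    rows = []
    seen: dict[tuple, str] = {}
    for seed_name, clusters in clusters_by_seed.items():
        for i, c in enumerate(clusters, start=1):
            name = f"{seed_name}_{i:02d}"
            key = tuple(np.round(c.peak_mni, 3))
            if key in seen:
                logger.warning(
                    "peak %s found for both %s and %s; keeping both nodes",
                    key, seen[key], name,
                )
            seen[key] = name
            rows.append(
                {
                    "node": name,
                    "seed": seed_name,
                    "x": c.peak_mni[0],
                    "y": c.peak_mni[1],
                    "z": c.peak_mni[2],
                    "radius_mm": radius_mm,
                    "peak_t": c.peak_t,
                    "cluster_size": c.size,
                }
            )
    if not rows:
        raise ValueError("no clusters survive; cannot build a node table")
    return pd.DataFrame(rows)


def extract_node_series(volume4d: np.ndarray, affine: np.ndarray, node_table: pd.DataFrame):
    """Mean series over each node's 3-mm sphere; returns a (T, N) array in
    node-table order."""
    volume4d = np.asarray(volume4d, float)
    out = np.empty((volume4d.shape[3], len(node_table)))
    for i, row in enumerate(node_table.itertuples(index=False)):
        vox = sphere_voxels(
            (row.x, row.y, row.z), getattr(row, "radius_mm", 3.0), affine, volume4d.shape[:3]
        )
        out[:, i] = volume4d[vox[:, 0], vox[:, 1], vox[:, 2]].mean(axis=0)
    return out


class SeedNodeIdentifier(BaseEstimator):
    """Estimator that learns network nodes from a cohort of 4-D volumes.

    Parameters
    ----------
    seeds : sequence of SeedSpec, default Broca + Wernicke.
    alpha : float, default 0.01
        Voxel-level FWE (Bonferroni) alpha for the one-sample t map.
    min_cluster_voxels : int, default 50
    gm_prob_threshold : float, default 0.9
    connectivity : {6, 18, 26}, default 26

    ``fit`` takes a list of 4-D arrays (one per subject, shared grid), the
    affine, and optionally a gray-matter probability map. Fitted attributes:
    ``nodes_`` (DataFrame of positive-tail nodes), ``negative_clusters_``,
    ``t_maps_`` (per seed).
    """

    def __init__(self, seeds=DEFAULT_SEEDS, alpha: float = 0.01,
                 min_cluster_voxels: int = 50, gm_prob_threshold: float = 0.9,
                 connectivity: int = 26):
        self.seeds = seeds
        self.alpha = alpha
        self.min_cluster_voxels = min_cluster_voxels
        self.gm_prob_threshold = gm_prob_threshold
        self.connectivity = connectivity

    def fit(self, volumes: list[np.ndarray], affine: np.ndarray, gm_mask=None):
        clusters_by_seed: dict[str, list[Cluster]] = {}
        neg_by_seed: dict[str, list[Cluster]] = {}
        self.t_maps_ = {}
        for seed in self.seeds:
            z_maps = [fisher_z(seed_fc_map(v, affine, seed)) for v in volumes]
            t_map = onesample_t_map(z_maps)
            self.t_maps_[seed.name] = t_map
            keep = fwe_voxel_threshold(t_map, self.alpha, gm_mask, self.gm_prob_threshold)
            pos = extract_clusters(keep & (t_map.values > 0), t_map,
                                   self.min_cluster_voxels, self.connectivity)
            neg = extract_clusters(keep & (t_map.values < 0), t_map,
                                   self.min_cluster_voxels, self.connectivity)
            clusters_by_seed[seed.name] = pos
            neg_by_seed[seed.name] = neg
            logger.info("seed %s: %d positive, %d negative clusters",
                        seed.name, len(pos), len(neg))
        self.nodes_ = build_node_table(clusters_by_seed)
        self.negative_clusters_ = neg_by_seed
        return self
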
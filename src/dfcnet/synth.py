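"""Synthetic multi-subject BOLD-like data with planted connectivity states.

The generator emulates the study conditions every downstream stage is
exercised against: two groups of 10 and 11 subjects, 170 retained volumes at
TR = 3 s, a 17-node network, and K = 4 latent connectivity states whose dwell
times are long relative to a 35-TR sliding window. Each state is a distinct
symmetric positive-definite (SPD) correlation matrix; at every TR a subject's
node vector is drawn from a zero-mean multivariate normal with the active
state's correlation matrix, plus independent white measurement noise. The
latent state sequence is a Markov chain shared across subjects, matching the
clustering layout downstream (one state label per window index across all
subjects). Group effects are planted as additive offsets on designated edges
in designated states.

A small 4-D volume phantom with planted seed-coupled clusters supports the
voxel-level node-identification stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import child_seed
from .series import SubjectSeries

logger = logging.getLogger("dfcnet")

__all__ = [
    "StateModel",
    "GroupEffect",
    "GroupEffectSpec",
    "SimulatedDataset",
    "VolumePhantom",
    "make_state_correlations",
    "apply_group_effects",
    "simulate_state_sequence",
    "simulate_subject",
    "simulate_dataset",
    "simulate_volume_phantom",
    "simulate_phantom_cohort",
    "default_group_effects",
    "window_true_states",
    "match_states",
]

_EIG_FLOOR = 0.05
_MAX_REPAIR = 10


# --------------------------------------------------------------------------
# state model
# --------------------------------------------------------------------------


@dataclass
class StateModel:
    """K latent connectivity states plus their Markov transition structure.

    ``correlations`` has shape (K, N, N); each slice is an SPD correlation
    matrix with unit diagonal. ``transition`` is K x K row-stochastic;
    ``mean_dwell`` is the expected consecutive TRs spent in a state.
    """

    correlations: np.ndarray
    transition: np.ndarray
    mean_dwell: float

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.correlations.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.correlations.shape[1]

    def validate(self) -> None:
        k, n, n2 = self.correlations.shape
        if n != n2:
            raise ValueError("correlation matrices must be square")
        for s in range(k):
            c = self.correlations[s]
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"state {s + 1} correlation matrix not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise ValueError(f"state {s + 1} diagonal not unit")
            off = c[~np.eye(n, dtype=bool)]
            if off.size and (np.abs(off) >= 1.0).any():
                raise ValueError(f"state {s + 1} off-diagonals not in (-1, 1)")
            if np.linalg.eigvalsh(c)[0] <= 0:
                raise ValueError(f"state {s + 1} correlation matrix not positive definite")
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape must be K x K")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if (self.transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if self.mean_dwell < 1:
            raise ValueError("mean_dwell must be >= 1 TR")

    def observed_correlations(self, noise_sd: float) -> np.ndarray:
        """State correlation matrices as seen through additive white noise.

        Independent noise of variance ``noise_sd**2`` on unit-variance signal
        attenuates every off-diagonal correlation by 1/(1 + noise_sd**2).
        """
        k = 1.0 / (1.0 + noise_sd**2)
        n = self.n_nodes
        eye = np.eye(n)
        return k * self.correlations + (1.0 - k) * eye

    def copy(self) -> "StateModel":
        return StateModel(self.correlations.copy(), self.transition.copy(), self.mean_dwell)


@dataclass(frozen=True)
class GroupEffect:
    """One planted group difference: edge (i, j), 1-based state, additive
    delta (in latent r units) received by group A."""

    node_i: int
    node_j: int
    state: int
    delta: float


@dataclass
class GroupEffectSpec:
    edges: list[GroupEffect] = field(default_factory=list)

    def validate(self, n_nodes: int, n_states: int) -> None:
        for e in self.edges:
            if e.node_i == e.node_j:
                raise ValueError("effect edge must join two distinct nodes")
            if not (0 <= e.node_i < n_nodes and 0 <= e.node_j < n_nodes):
                raise ValueError("effect node index out of range")
            if not (1 <= e.state <= n_states):
                raise ValueError(f"effect state {e.state} outside 1..{n_states}")


def _repair_correlation(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to an SPD correlation matrix: floor the
    spectrum at 0.05 and rescale to unit diagonal."""
    w, v = np.linalg.eigh(c)
    w = np.maximum(w, _EIG_FLOOR)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 1.0)
    return c


def _modular_correlation(
    n: int, base_strength: float, rng: np.random.Generator, n_modules: int
) -> np.ndarray:
    """One modular correlation matrix: a random partition of the nodes into
    modules, within-module correlation ``base_strength``, weak cross-module
    background, SPD-repaired."""
    if base_strength == 0:
        return np.eye(n)
    r_out = base_strength / 14.0
    # random partition with every module non-empty where possible
    assign = rng.permutation(np.arange(n) % n_modules)
    c = np.full((n, n), r_out)
    for m in range(n_modules):
        idx = np.flatnonzero(assign == m)
        c[np.ix_(idx, idx)] = base_strength
    np.fill_diagonal(c, 1.0)
    return _repair_correlation(c)


def make_state_correlations(
    n_nodes: int = 17,
    n_states: int = 4,
    base_strength: float = 0.7,
    rng_seed: int = 0,
    mean_dwell: float = 50.0,
    n_modules: int = 3,
) -> StateModel:
    """Build K distinct SPD correlation matrices plus a Markov transition
    matrix with self-transition probability ``1 - 1/mean_dwell``.

    Each state is modular: a state-specific random partition of the nodes
    into ``n_modules`` communities with within-module correlation
    ``base_strength`` and a weak cross-module background, SPD-repaired by
    eigenvalue flooring at 0.05. Modular states emulate the distinct
    connectivity patterns dFC states represent and differ strongly edgewise,
    so they remain distinguishable through windowed-correlation sampling
    noise. ``base_strength`` = 0 yields the identity (uncoupled nodes).
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if not (0 <= base_strength < 1):
        raise ValueError("base_strength must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    n_modules = max(1, min(n_modules, n_nodes))
    mats = np.empty((n_states, n_nodes, n_nodes))
    for s in range(n_states):
        ok = False
        for _ in range(_MAX_REPAIR):
            c = _modular_correlation(n_nodes, base_strength, rng, n_modules)
            if np.linalg.eigvalsh(c)[0] > 0:
                ok = True
                break
        if not ok:
            raise RuntimeError(f"could not construct an SPD correlation matrix for state {s + 1}")
        # keep states pairwise distinct (redraw on a partition collision,
        # then fall back to a small jitter for very small node sets)
        if base_strength > 0:
            for _ in range(_MAX_REPAIR):
                if all(np.linalg.norm(c - mats[p]) > 1e-9 for p in range(s)):
                    break
                c = _modular_correlation(n_nodes, base_strength, rng, n_modules)
            else:
                jit = rng.normal(0.0, 0.02, size=(n_nodes, n_nodes))
                c = _repair_correlation(c + 0.5 * (jit + jit.T))
                if any(np.linalg.norm(c - mats[p]) <= 1e-9 for p in range(s)):
                    raise RuntimeError(
                        f"could not make state {s + 1} distinct from earlier states"
                    )
        mats[s] = c
    if n_states == 1:
        trans = np.array([[1.0]])
    else:
        p_stay = 1.0 - 1.0 / mean_dwell
        p_off = (1.0 - p_stay) / (n_states - 1)
        trans = np.full((n_states, n_states), p_off)
        np.fill_diagonal(trans, p_stay)
    return StateModel(mats, trans, mean_dwell)


def apply_group_effects(
    model: StateModel, effects: GroupEffectSpec | list[GroupEffect], group: str
) -> StateModel:
    """Return the group-specific state model.

    Group "A" receives ``+delta`` on each listed edge in its listed state;
    group "B" gets the model unchanged. If a perturbation breaks positive
    definiteness the deltas for that state are halved (up to 10 times) before
    giving up.
    """
    if isinstance(effects, list):
        effects = GroupEffectSpec(list(effects))
    effects.validate(model.n_nodes, model.n_states)
    out = model.copy()
    if group == "B" or not effects.edges:
        return out
    if group != "A":
        raise ValueError("group must be 'A' or 'B'")
    by_state: dict[int, list[GroupEffect]] = {}
    for e in effects.edges:
        by_state.setdefault(e.state, []).append(e)
    for state, edges in by_state.items():
        base = model.correlations[state - 1]
        scale = 1.0
        for _ in range(_MAX_REPAIR + 1):
            c = base.copy()
            for e in edges:
                c[e.node_i, e.node_j] += scale * e.delta
                c[e.node_j, e.node_i] += scale * e.delta
            off_ok = np.all(np.abs(c[~np.eye(model.n_nodes, dtype=bool)]) < 1.0)
            if off_ok and np.linalg.eigvalsh(c)[0] > 0:
                if scale < 1.0:
                    logger.warning(
                        "group effect in state %d shrunk to %.3g of nominal to keep SPD",
                        state,
                        scale,
                    )
                out.correlations[state - 1] = c
                break
            scale *= 0.5
        else:
            raise RuntimeError(f"group effect destroys positive definiteness in state {state}")
    return out


def simulate_state_sequence(
    n_timepoints: int, transition: np.ndarray, rng_seed: int = 0
) -> np.ndarray:
    """Sample a 1-based Markov state-label sequence of length ``n_timepoints``.

    The initial state is uniform over states; reproducible given the seed.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    transition = np.asarray(transition, dtype=float)
    k = transition.shape[0]
    rng = np.random.default_rng(rng_seed)
    cum = np.cumsum(transition, axis=1)
    states = np.empty(n_timepoints, dtype=int)
    s = int(rng.integers(k))
    states[0] = s
    u = rng.random(n_timepoints)
    for t in range(1, n_timepoints):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, k - 1)
        states[t] = s
    return states + 1


def simulate_balanced_sequence(
    n_timepoints: int, n_states: int, rng_seed: int = 0
) -> np.ndarray:
    """One contiguous visit per state in seed-shuffled order, segment
    lengths as equal as possible (1-based labels).

    This is the default dataset sequence: with 170 TRs and 4 states each
    segment lasts 42-43 TRs, longer than the 35-TR analysis window, and
    every planted state is guaranteed to occur — a geometric-dwell Markov
    chain over so short a scan frequently never visits some states, which
    would make the planted state count unrecoverable by construction.
    """
    if n_timepoints < n_states:
        raise ValueError("need at least one TR per state")
    rng = np.random.default_rng(rng_seed)
    lens = np.full(n_states, n_timepoints // n_states)
    lens[: n_timepoints % n_states] += 1
    order = rng.permutation(n_states)
    return np.repeat(order + 1, lens[order])


def simulate_subject(
    model: StateModel,
    true_states: np.ndarray,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
    tr_seconds: float = 3.0,
    node_names: list[str] | None = None,
    subject_id: str = "sim",
    group: str | None = None,
) -> SubjectSeries:
    """Draw one subject's series: per TR a zero-mean MVN sample with the
    active state's correlation matrix, plus independent N(0, noise_sd^2)
    measurement noise on every node."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    true_states = np.asarray(true_states, dtype=int)
    t = true_states.shape[0]
    n = model.n_nodes
    rng = np.random.default_rng(rng_seed)
    chol = np.stack([np.linalg.cholesky(model.correlations[s]) for s in range(model.n_states)])
    z = rng.standard_normal((t, n))
    # y_t = L_{s(t)} z_t, batched over TRs by state
    y = np.einsum("tij,tj->ti", chol[true_states - 1], z)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal((t, n))
    return SubjectSeries(
        values=y,
        tr_seconds=tr_seconds,
        node_names=node_names or [],
        subject_id=subject_id,
        group=group,
    )


# --------------------------------------------------------------------------
# whole-dataset simulation
# --------------------------------------------------------------------------


def default_group_effects(node_names: list[str] | None = None) -> GroupEffectSpec:
    """Default planted group differences: four edges across states 1-3 with
    delta = +0.60 in latent r units.

    The latent delta is deliberately larger than the group differences the
    analysis reports (~0.25-0.45 in r units): measurement noise attenuates
    windowed correlations by 1/(1 + noise_sd^2) = 0.8 and state-mixed
    windows dilute the state-conditional difference further, so a latent
    0.60 surfaces as an observed state-mean difference near 0.3 with
    pipeline-measured effect sizes around d = 2."""
    if node_names is None:
        from .fixtures import default_node_names

        node_names = default_node_names()
    idx = {name: i for i, name in enumerate(node_names)}

    def _edge(a: str, b: str, state: int) -> GroupEffect:
        return GroupEffect(idx[a], idx[b], state, 0.60)

    if all(n in idx for n in ("MTG.L", "MTG.R", "IFGoperc.R", "MFG.R", "IFGtriang.R", "TPOsup.R")):
        return GroupEffectSpec(
            [
                _edge("MTG.L", "MTG.R", 1),
                _edge("IFGoperc.R", "MFG.R", 1),
                _edge("MTG.L", "IFGtriang.R", 2),
                _edge("TPOsup.R", "MTG.L", 3),
            ]
        )
    # generic fallback for small node sets
    return GroupEffectSpec([GroupEffect(0, 1, 1, 0.60)])


@dataclass
class SimulatedDataset:
    """A full two-group synthetic cohort plus its generating truth."""

    subjects: list[SubjectSeries]
    group_labels: list[str]
    true_states: np.ndarray
    seed: int
    model_a: StateModel
    model_b: StateModel
    effects: GroupEffectSpec
    noise_sd: float

    @property
    def n_states(self) -> int:
        return self.model_b.n_states

    def series_arrays(self) -> np.ndarray:
        return np.stack([s.values for s in self.subjects])

    def write(self, out_dir: str | Path) -> None:
        """Persist series as TSV plus a JSON manifest with the planted truth."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            s.to_tsv(out_dir / f"{s.subject_id}.tsv")
        manifest = {
            "seed": self.seed,
            "tr_seconds": self.subjects[0].tr_seconds,
            "noise_sd": self.noise_sd,
            "n_states": self.n_states,
            "node_names": self.subjects[0].node_names,
            "subjects": [
                {"subject_id": s.subject_id, "group": g, "file": f"{s.subject_id}.tsv"}
                for s, g in zip(self.subjects, self.group_labels)
            ],
            "true_states": self.true_states.tolist(),
            "effects": [
                {"node_i": e.node_i, "node_j": e.node_j, "state": e.state, "delta": e.delta}
                for e in self.effects.edges
            ],
        }
        from ._utils import atomic_write_text

        atomic_write_text(out_dir / "manifest.json", json.dumps(manifest, indent=1))

    @classmethod
    def read(cls, in_dir: str | Path) -> "SimulatedDataset":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        subjects = []
        for rec in manifest["subjects"]:
            subjects.append(
                SubjectSeries.from_tsv(
                    in_dir / rec["file"],
                    tr_seconds=manifest["tr_seconds"],
                    subject_id=rec["subject_id"],
                    group=rec["group"],
                )
            )
        effects = GroupEffectSpec(
            [
                GroupEffect(e["node_i"], e["node_j"], e["state"], e["delta"])
                for e in manifest["effects"]
            ]
        )
        n = len(manifest["node_names"])
        k = manifest["n_states"]
        # models are not persisted; rebuild placeholders for truth-only use
        placeholder = StateModel(
            np.broadcast_to(np.eye(n), (k, n, n)).copy(), np.full((k, k), 1.0 / k), 1.0
        )
        return cls(
            subjects=subjects,
            group_labels=[rec["group"] for rec in manifest["subjects"]],
            true_states=np.asarray(manifest["true_states"], dtype=int),
            seed=manifest["seed"],
            model_a=placeholder,
            model_b=placeholder,
            effects=effects,
            noise_sd=manifest["noise_sd"],
        )


def simulate_dataset(
    n_group_a: int = 10,
    n_group_b: int = 11,
    n_timepoints: int = 170,
    n_nodes: int = 17,
    n_states: int = 4,
    mean_dwell: float = 50.0,
    base_strength: float = 0.6,
    noise_sd: float = 0.5,
    effects: GroupEffectSpec | None = None,
    node_names: list[str] | None = None,
    tr_seconds: float = 3.0,
    sequence: str = "balanced",
    rng_seed: int = 0,
) -> SimulatedDataset:
    """Simulate the default two-group cohort.

    Defaults reproduce the study conditions end-to-end: 10 + 11 subjects,
    170 TRs at TR = 3 s, 17 nodes (fixture names), 4 modular states,
    measurement noise SD 0.5, and four planted group-difference edges.
    The shared latent sequence is "balanced" by default (one 42-43 TR
    segment per state, shuffled order); ``sequence="markov"`` samples a
    geometric-dwell chain with ``mean_dwell`` instead. Before group effects
    are applied, each planted edge's baseline in its target state is lowered
    to the cross-module background, so the lower group sits near zero and
    the higher group near ``delta`` — the pattern the reported group tables
    show. All randomness derives from ``rng_seed`` via counter-based child
    seeds, so any stage can be reproduced in isolation.
    """
    if node_names is None and n_nodes == 17:
        from .fixtures import default_node_names

        node_names = default_node_names()
    if node_names is None:
        node_names = [f"node_{i + 1:02d}" for i in range(n_nodes)]
    model = make_state_correlations(
        n_nodes=n_nodes,
        n_states=n_states,
        base_strength=base_strength,
        rng_seed=child_seed(rng_seed, "state-model"),
        mean_dwell=mean_dwell,
    )
    if effects is None:
        effects = default_group_effects(node_names)
    effects.validate(n_nodes, n_states)
    # detach each planted edge's endpoints from their modules in the target
    # state (rows drop to the cross-module background) so the edge starts
    # from a weak baseline and +delta keeps the matrix SPD even for strong
    # effects; the perturbation then only involves the near-isolated pair
    baseline = base_strength / 14.0
    for e in effects.edges:
        c = model.correlations[e.state - 1]
        for node in (e.node_i, e.node_j):
            c[node, :] = baseline
            c[:, node] = baseline
            c[node, node] = 1.0
        model.correlations[e.state - 1] = _repair_correlation(c)
    model_a = apply_group_effects(model, effects, "A")
    model_b = apply_group_effects(model, effects, "B")
    if sequence == "balanced":
        true_states = simulate_balanced_sequence(
            n_timepoints, n_states, rng_seed=child_seed(rng_seed, "state-sequence")
        )
    elif sequence == "markov":
        true_states = simulate_state_sequence(
            n_timepoints, model.transition, rng_seed=child_seed(rng_seed, "state-sequence")
        )
    else:
        raise ValueError("sequence must be 'balanced' or 'markov'")
    subjects: list[SubjectSeries] = []
    groups: list[str] = []
    for i in range(n_group_a + n_group_b):
        group = "A" if i < n_group_a else "B"
        m = model_a if group == "A" else model_b
        subjects.append(
            simulate_subject(
                m,
                true_states,
                noise_sd=noise_sd,
                rng_seed=child_seed(rng_seed, 1000 + i),
                tr_seconds=tr_seconds,
                node_names=node_names,
                subject_id=f"sub-{i + 1:02d}",
                group=group,
            )
        )
        groups.append(group)
    return SimulatedDataset(
        subjects=subjects,
        group_labels=groups,
        true_states=true_states,
        seed=rng_seed,
        model_a=model_a,
        model_b=model_b,
        effects=effects,
        noise_sd=noise_sd,
    )


# --------------------------------------------------------------------------
# truth-matching helpers for recovery evaluation
# --------------------------------------------------------------------------


def window_true_states(true_states: np.ndarray, window_starts: np.ndarray, length: int) -> np.ndarray:
    """Majority planted state per sliding window (1-based labels)."""
    true_states = np.asarray(true_states, dtype=int)
    out = np.empty(len(window_starts), dtype=int)
    for w, start in enumerate(window_starts):
        seg = true_states[start : start + length]
        vals, counts = np.unique(seg, return_counts=True)
        out[w] = vals[np.argmax(counts)]
    return out


def match_states(pred_labels: np.ndarray, true_labels: np.ndarray) -> dict[int, int]:
    """Map every predicted state label to a planted label.

    One-to-one Hungarian assignment on the window-overlap confusion matrix;
    surplus predicted labels (when more states were found than planted) fall
    back to their individually best-overlapping planted state.
    """
    from scipy.optimize import linear_sum_assignment

    pred_vals = np.unique(pred_labels)
    true_vals = np.unique(true_labels)
    conf = np.zeros((len(pred_vals), len(true_vals)))
    for a, p in enumerate(pred_vals):
        for b, t in enumerate(true_vals):
            conf[a, b] = np.sum((pred_labels == p) & (true_labels == t))
    rows, cols = linear_sum_assignment(-conf)
    mapping = {int(pred_vals[r]): int(true_vals[c]) for r, c in zip(rows, cols)}
    for a, p in enumerate(pred_vals):
        if int(p) not in mapping:
            mapping[int(p)] = int(true_vals[int(np.argmax(conf[a]))])
    return mapping


# --------------------------------------------------------------------------
# voxel-level phantom
# --------------------------------------------------------------------------


@dataclass
class VolumePhantom:
    """A small 4-D volume with planted seed-coupled clusters.

    ``data`` is (x, y, z, t); ``gm_mask`` is a 3-D gray-matter probability
    map; ``planted_clusters`` records (center MNI, voxel count, coupling).
    """

    data: np.ndarray
    affine: np.ndarray
    gm_mask: np.ndarray
    planted_clusters: list[tuple[tuple[float, float, float], int, float]]
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("phantom data must be finite")
        if self.gm_mask.shape != self.data.shape[:3]:
            raise ValueError("gm_mask shape must match the spatial grid")

    def to_nifti(self, data_path: str | Path, mask_path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(data_path))
        nib.save(nib.Nifti1Image(self.gm_mask.astype(np.float32), self.affine), str(mask_path))


def _grid_affine(node_xyz: np.ndarray, grid_shape: tuple[int, int, int], voxel_mm: float) -> np.ndarray:
    """3-mm isotropic affine positioning the grid around the node bounding box."""
    lo = node_xyz.min(axis=0)
    hi = node_xyz.max(axis=0)
    center = (lo + hi) / 2.0
    origin = center - voxel_mm * (np.asarray(grid_shape) - 1) / 2.0
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_mm
    aff[:3, 3] = origin
    return aff


def simulate_volume_phantom(
    node_table,
    grid_shape: tuple[int, int, int] = (20, 20, 16),
    seed_specs=None,
    rng_seed: int = 0,
    n_timepoints: int = 80,
    cluster_voxels: int = 60,
    coupling: float = 0.8,
    noise_sd: float = 1.0,
    voxel_mm: float = 3.0,
    tr_seconds: float = 3.0,
    latent_signals: dict[str, np.ndarray] | None = None,
) -> VolumePhantom:
    """Build one subject's 4-D phantom on a 3-mm grid.

    Each seed sphere carries a unit-variance latent signal plus noise; each
    node in ``node_table`` becomes a compact blob of ``cluster_voxels``
    voxels whose signal is ``coupling * latent(seed-of-origin) + noise``.
    Background voxels are pure noise. The gray-matter probability map is
    0.98 inside the grid interior, 0 on the one-voxel border.

    ``latent_signals`` (one unit-variance series per seed name) may be
    supplied to share seed signals across a cohort; by default they are drawn
    per call.
    """
    from .nodes import DEFAULT_SEEDS, sphere_voxels

    if seed_specs is None:
        seed_specs = DEFAULT_SEEDS
    rng = np.random.default_rng(rng_seed)
    node_xyz = node_table[["x", "y", "z"]].to_numpy(dtype=float)
    seed_xyz = np.array([s.center_mni for s in seed_specs], dtype=float)
    affine = _grid_affine(np.vstack([node_xyz, seed_xyz]), grid_shape, voxel_mm)
    inv = np.linalg.inv(affine)

    def to_voxel(xyz):
        return (inv[:3, :3] @ np.asarray(xyz, dtype=float) + inv[:3, 3])

    for xyz in np.vstack([node_xyz, seed_xyz]):
        v = to_voxel(xyz)
        if np.any(v < 0) or np.any(v > np.asarray(grid_shape) - 1):
            raise ValueError(f"coordinate {tuple(xyz)} falls outside the phantom grid")

    if latent_signals is None:
        latent_signals = {
            s.name: rng.standard_normal(n_timepoints) for s in seed_specs
        }
    data = noise_sd * rng.standard_normal((*grid_shape, n_timepoints))

    # seed spheres carry their latent signal
    for s in seed_specs:
        vox = sphere_voxels(s.center_mni, s.radius_mm, affine, grid_shape)
        for ijk in vox:
            data[tuple(ijk)] += latent_signals[s.name]

    # planted node clusters: nearest lattice points around each peak
    grid_idx = np.indices(grid_shape).reshape(3, -1).T
    grid_mm = grid_idx @ affine[:3, :3].T + affine[:3, 3]
    planted = []
    seed_of = node_table["seed"].tolist()
    for row_i in range(len(node_table)):
        center = node_xyz[row_i]
        d2 = np.sum((grid_mm - center) ** 2, axis=1)
        order = np.argsort(d2, kind="stable")[:cluster_voxels]
        sig = latent_signals[seed_of[row_i]]
        # quadratic coupling taper (70% at the blob edge) so the t peak sits
        # at the planted center rather than anywhere in the blob
        d_max = max(np.sqrt(d2[order[-1]]), 1e-9)
        for flat in order:
            taper = 1.0 - 0.3 * (d2[flat] / d_max**2)
            data[tuple(grid_idx[flat])] += coupling * taper * sig
        planted.append((tuple(center), int(cluster_voxels), float(coupling)))

    gm = np.zeros(grid_shape)
    gm[1:-1, 1:-1, 1:-1] = 0.98
    return VolumePhantom(data=data, affine=affine, gm_mask=gm,
                         planted_clusters=planted, tr_seconds=tr_seconds)


def simulate_phantom_cohort(
    node_table,
    n_subjects: int = 8,
    rng_seed: int = 0,
    **kwargs,
) -> list[VolumePhantom]:
    """A cohort of phantoms on a shared grid, independent draws per subject."""
    return [
        simulate_volume_phantom(node_table, rng_seed=child_seed(rng_seed, 2000 + i), **kwargs)
        for i in range(n_subjects)
    ]
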
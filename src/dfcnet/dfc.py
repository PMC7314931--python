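"""Sliding-window dynamic functional connectivity.

The scan is segmented into overlapping rectangular windows (35 TRs, step 1
by default; 170 retained TRs yield 136 windows). Within each window the
Pearson correlation between every node pair is computed with window-local
means and SDs, giving one edge vector of length E = N(N-1)/2 per window per
subject, ordered upper-triangle row-major over the node table. Stacking all
subjects' edge vectors window-by-window (subject-major columns) builds the
W x (S*E) dynamic matrix whose rows are the samples later clustered into
dFC states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .series import SubjectSeries

logger = logging.getLogger("dfcnet")

__all__ = [
    "WindowSpec",
    "DynamicMatrix",
    "window_indices",
    "window_correlations",
    "build_dynamic_matrix",
    "SlidingWindowConnectivity",
    "edge_names",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in TR units (length 35, step 1 by default)."""

    length_tr: int = 35
    step_tr: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.step_tr <= self.length_tr):
            raise ValueError("need 1 <= step <= length")

    def n_windows(self, n_timepoints: int) -> int:
        if self.length_tr > n_timepoints:
            raise ValueError(
                f"window length {self.length_tr} exceeds series length {n_timepoints}"
            )
        return (n_timepoints - self.length_tr) // self.step_tr + 1


def window_indices(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """0-based half-open (start, end) TR intervals for each sliding window."""
    w = spec.n_windows(n_timepoints)
    return [(i * spec.step_tr, i * spec.step_tr + spec.length_tr) for i in range(w)]


def edge_names(node_names: list[str]) -> list[str]:
    """Edge labels in upper-triangle row-major order."""
    iu, ju = np.triu_indices(len(node_names), k=1)
    return [f"{node_names[i]}--{node_names[j]}" for i, j in zip(iu, ju)]


def window_correlations(series, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Per-window Pearson correlations for one subject.

    Returns a (W, E) array of upper-triangle correlations, E = N(N-1)/2.
    A node with zero variance inside a window contributes r = 0 on its edges
    (counted and logged).
    """
    values = series.values if isinstance(series, SubjectSeries) else np.asarray(series, float)
    t, n = values.shape
    if spec.length_tr < 3:
        raise ValueError("window length must be >= 3 for correlation")
    win = sliding_window_view(values, spec.length_tr, axis=0)[:: spec.step_tr]
    # win: (W, N, L)
    w = win.shape[0]
    mean = win.mean(axis=2, keepdims=True)
    dev = win - mean
    ss = np.einsum("wnl,wnl->wn", dev, dev)
    sd = np.sqrt(ss)
    zero_var = sd <= 0
    n_zero = int(zero_var.sum())
    if n_zero:
        logger.warning("%d zero-variance node-windows; their edges set to r=0", n_zero)
    safe_sd = np.where(zero_var, 1.0, sd)
    cov = np.einsum("wnl,wml->wnm", dev, dev)
    corr = cov / (safe_sd[:, :, None] * safe_sd[:, None, :])
    corr = np.where(zero_var[:, :, None] | zero_var[:, None, :], 0.0, corr)
    corr = np.clip(corr, -1.0, 1.0)
    iu, ju = np.triu_indices(n, k=1)
    return np.ascontiguousarray(corr[:, iu, ju])


@dataclass
class DynamicMatrix:
    """W x (S*E) matrix of windowed correlations, subject-major columns."""

    values: np.ndarray
    window_starts: np.ndarray
    subject_order: list[str]
    n_nodes: int
    spec: WindowSpec = field(default_factory=WindowSpec)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def n_subjects(self) -> int:
        return len(self.subject_order)

    def subject_block(self, subject: int | str) -> np.ndarray:
        """(W, E) slice for one subject."""
        if isinstance(subject, str):
            subject = self.subject_order.index(subject)
        e = self.n_edges
        return self.values[:, subject * e : (subject + 1) * e]

    def per_subject_array(self) -> np.ndarray:
        """(S, W, E) view of the matrix."""
        w = self.n_windows
        return self.values.reshape(w, self.n_subjects, self.n_edges).transpose(1, 0, 2)


def build_dynamic_matrix(
    window_corrs: list[np.ndarray],
    subject_ids: list[str] | None = None,
    n_nodes: int | None = None,
    spec: WindowSpec = WindowSpec(),
) -> DynamicMatrix:
    """Concatenate per-subject (W, E) windowed-correlation arrays into the
    clustering matrix: row w holds subject 1..S edge vectors for window w."""
    if not window_corrs:
        raise ValueError("no subjects supplied")
    shapes = {a.shape for a in window_corrs}
    if len(shapes) != 1:
        for i, a in enumerate(window_corrs):
            if a.shape != window_corrs[0].shape:
                name = subject_ids[i] if subject_ids else f"#{i}"
                raise ValueError(
                    f"subject {name} has window array shape {a.shape}, "
                    f"expected {window_corrs[0].shape}"
                )
    w, e = window_corrs[0].shape
    if n_nodes is None:
        # invert E = N(N-1)/2
        n_nodes = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(len(window_corrs))]
    values = np.concatenate(window_corrs, axis=1)
    starts = np.arange(w) * spec.step_tr
    return DynamicMatrix(
        values=values,
        window_starts=starts,
        subject_order=list(subject_ids),
        n_nodes=n_nodes,
        spec=spec,
    )


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from subject time series to the dynamic matrix.

    Parameters
    ----------
    window_length_tr : int, default 35
    window_step_tr : int, default 1

    ``transform`` accepts a list of SubjectSeries (or T x N arrays) sharing
    T and N and returns a :class:`DynamicMatrix`.
    """

    def __init__(self, window_length_tr: int = 35, window_step_tr: int = 1):
        self.window_length_tr = window_length_tr
        self.window_step_tr = window_step_tr

    def _spec(self) -> WindowSpec:
        return WindowSpec(self.window_length_tr, self.window_step_tr)

    def fit(self, X, y=None):
        self._spec()
        return self

    def transform(self, X) -> DynamicMatrix:
        spec = self._spec()
        if not isinstance(X, list):
            X = [X]
        ids = [
            x.subject_id if isinstance(x, SubjectSeries) else f"sub-{i + 1:02d}"
            for i, x in enumerate(X)
        ]
        n_nodes = (
            X[0].n_nodes if isinstance(X[0], SubjectSeries) else np.asarray(X[0]).shape[1]
        )
        corrs = [window_correlations(x, spec) for x in X]
        return build_dynamic_matrix(corrs, subject_ids=ids, n_nodes=n_nodes, spec=spec)
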
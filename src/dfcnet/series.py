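"""Per-subject node time-series container and TSV round-tripping.

The central in-memory object downstream of node identification is one
``SubjectSeries`` per subject: a T x N matrix of node signals sampled every
``tr_seconds`` seconds, with named nodes and a group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SubjectSeries:
    """One subject's node-by-time signal matrix.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        Signal values, rows are time points (TRs), columns are nodes.
    tr_seconds : float
        Sampling interval in seconds (repetition time).
    node_names : list of str
        Unique node labels, length N.
    subject_id : str
    group : str or None
        Group label (e.g. "A"/"B").
    """

    values: np.ndarray
    tr_seconds: float = 3.0
    node_names: list[str] = field(default_factory=list)
    subject_id: str = "subject"
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T x N) array")
        if not self.node_names:
            self.node_names = [f"node_{i + 1:02d}" for i in range(self.values.shape[1])]
        self.node_names = list(self.node_names)
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"series must be at least 2 x 2, got {t} x {n}")
        if len(self.node_names) != n:
            raise ValueError("node_names length must match number of columns")
        if len(set(self.node_names)) != n:
            raise ValueError("node_names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SubjectSeries":
        """Copy of this series with new values (same nodes and metadata)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.node_names)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        tr_seconds: float = 3.0,
        subject_id: str | None = None,
        group: str | None = None,
    ) -> "SubjectSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            values=df.to_numpy(dtype=float),
            tr_seconds=tr_seconds,
            node_names=list(df.columns),
            subject_id=subject_id or Path(path).stem,
            group=group,
        )
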
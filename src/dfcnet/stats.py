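"""Group inference: permutation tests, max-statistic FWE, Cohen's d.

Group differences (edge strength within a state, or a graph metric within a
state) are tested with a nonparametric two-sample permutation test on the
absolute mean difference (the two-tailed statistic), 5,000 label
permutations by default. When the number of distinct group assignments is
at most ``n_perm`` the null is enumerated exactly. Family-wise error across
a family of comparisons (all edges within a state; all states within a
metric) is controlled with a single-step max-statistic correction that
reuses the same permutations, each member standardized by its permutation
SD. Effect sizes are pooled-SD Cohen's d.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

logger = logging.getLogger("dfcnet")

__all__ = [
    "cohens_d",
    "cohens_d_from_samples",
    "permutation_test",
    "fwe_max_stat",
    "compare_states",
]


def cohens_d(mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int) -> float:
    """Pooled-SD Cohen's d from summary statistics.

    d = (mean_a - mean_b) / s_p,
    s_p = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2)).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if sp == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((mean_a - mean_b) / sp)


def cohens_d_from_samples(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return cohens_d(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


def _perm_index_matrix(n: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """(P, n) permutation matrix of pooled indices; first n_a columns form
    the permuted group A. Exact enumeration when feasible."""
    total = comb(n, n_a)
    if total <= n_perm:
        rows = []
        all_idx = set(range(n))
        for a_idx in combinations(range(n), n_a):
            rest = sorted(all_idx - set(a_idx))
            rows.append(list(a_idx) + rest)
        return np.asarray(rows, dtype=int), True
    keys = rng.random((n_perm, n))
    return np.argsort(keys, axis=1), False


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    rng_seed: int = 0,
) -> float:
    """Two-tailed permutation p-value for the group mean difference.

    Statistic: |mean(A) - mean(B)|. Group labels are re-assigned preserving
    group sizes. If C(n, n_a) <= n_perm the assignment null is enumerated
    exactly (p = #{perm stat >= observed} / total, observed included);
    otherwise Monte-Carlo with the +1 convention so p is never 0.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    obs = abs(a.mean() - b.mean())
    if np.ptp(pooled) == 0:
        return 1.0
    rng = np.random.default_rng(rng_seed)
    idx, exact = _perm_index_matrix(n, n_a, n_perm, rng)
    # sorting makes the sampled null invariant to within-group reordering
    perm_vals = np.sort(pooled)[idx]
    diffs = np.abs(perm_vals[:, :n_a].mean(axis=1) - perm_vals[:, n_a:].mean(axis=1))
    tol = 1e-12 * max(1.0, obs)
    if exact:
        return float(np.mean(diffs >= obs - tol))
    return float((1 + np.sum(diffs >= obs - tol)) / (1 + len(diffs)))


def fwe_max_stat(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-step max-statistic FWE correction over a family of comparisons.

    Parameters
    ----------
    values_a : (n_a, M) array — group A subjects by family members.
    values_b : (n_b, M) array.

    Each permutation relabels subjects once for the whole family; member
    statistics are standardized by their permutation SD and the maximum over
    members forms the FWE null. Returns ``(p_raw, p_fwe)`` arrays of length
    M (both with the +1 convention; exact enumeration when feasible).
    """
    a = np.atleast_2d(np.asarray(values_a, float))
    b = np.atleast_2d(np.asarray(values_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the family of comparisons")
    n_a = a.shape[0]
    pooled = np.vstack([a, b])
    n = pooled.shape[0]
    obs = np.abs(a.mean(axis=0) - b.mean(axis=0))
    rng = np.random.default_rng(rng_seed)
    idx, exact = _perm_index_matrix(n, n_a, n_perm, rng)
    perm = pooled[idx]  # (P, n, M)
    diffs = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))  # (P, M)
    sd = diffs.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = diffs / sd
    max_z = z.max(axis=1)  # (P,)
    obs_z = obs / sd
    tol = 1e-12
    if exact:
        p_raw = np.mean(diffs >= obs[None, :] - tol, axis=0)
        p_fwe = np.mean(max_z[:, None] >= obs_z[None, :] - tol, axis=0)
    else:
        p_raw = (1 + np.sum(diffs >= obs[None, :] - tol, axis=0)) / (1 + diffs.shape[0])
        p_fwe = (1 + np.sum(max_z[:, None] >= obs_z[None, :] - tol, axis=0)) / (1 + diffs.shape[0])
    return np.asarray(p_raw, float), np.asarray(p_fwe, float)


def compare_states(
    state_values: np.ndarray,
    groups: list[str],
    member_names: list[str],
    state_of_member: np.ndarray | None = None,
    n_perm: int = 5000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Member-wise group comparison within each state family.

    Parameters
    ----------
    state_values : (S_subjects, K, M) array
        Per-subject summaries: K states by M members (edges, or metrics).
    groups : per-subject group labels ("A"/"B").
    member_names : length-M labels.
    state_of_member : optional; unused placeholder for ragged designs.

    For each state, the M members form one FWE family (single-step max-T
    over the same subject relabelings). Subjects missing a state (NaN) are
    dropped from that state's family (logged). Returns a tidy table with
    group means/SDs, observed difference, raw and FWE-adjusted permutation
    p-values, and Cohen's d.
    """
    vals = np.asarray(state_values, float)
    if vals.ndim != 3:
        raise ValueError("state_values must be (subjects, states, members)")
    groups = np.asarray(groups)
    is_a = groups == "A"
    is_b = groups == "B"
    if is_a.sum() < 2 or is_b.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    k = vals.shape[1]
    rows = []
    for state in range(1, k + 1):
        sv = vals[:, state - 1, :]  # (S, M)
        present = ~np.isnan(sv).any(axis=1)
        if (~present).any():
            logger.info(
                "state %d: dropping %d subject(s) with no windows in this state",
                state, int((~present).sum()),
            )
        a = sv[present & is_a]
        b = sv[present & is_b]
        if len(a) < 2 or len(b) < 2:
            logger.warning("state %d skipped: fewer than 2 subjects per group", state)
            continue
        p_raw, p_fwe = fwe_max_stat(a, b, n_perm=n_perm, rng_seed=rng_seed + state)
        for m, name in enumerate(member_names):
            try:
                d = cohens_d_from_samples(a[:, m], b[:, m])
            except ValueError:
                d = np.nan
            rows.append(
                {
                    "state": state,
                    "member": name,
                    "mean_a": a[:, m].mean(),
                    "sd_a": a[:, m].std(ddof=1),
                    "mean_b": b[:, m].mean(),
                    "sd_b": b[:, m].std(ddof=1),
                    "diff": a[:, m].mean() - b[:, m].mean(),
                    "p_perm": p_raw[m],
                    "p_fwe": p_fwe[m],
                    "d": d,
                }
            )
    return pd.DataFrame(rows)
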
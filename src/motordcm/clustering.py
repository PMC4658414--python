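"""Ward hierarchical clustering of connectivity parameters.

Agglomerative clustering with Ward's minimum-variance criterion and squared
Euclidean proximity, reported as an SPSS-style agglomeration schedule whose
coefficient after each merge is the cumulative total within-cluster sum of
squares (the first merge of singletons a, b contributes d2(a, b)/2).  The
number of clusters is chosen at the largest relative jump ("elbow") of the
schedule among the last merges; membership comes from cutting the tree at
that count.

Features are left unstandardised by default (the convention of the
statistics package this schedule mirrors); pass ``zscore=True`` to scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


@dataclass(frozen=True)
class AgglomerationSchedule:
    """Merge order and cumulative within-cluster SS coefficients."""

    merges: np.ndarray = field(repr=False)  # (n-1, 2) scipy cluster ids
    heights: np.ndarray = field(repr=False)  # scipy ward heights
    coefficients: np.ndarray = field(repr=False)  # cumulative total within-SS
    n: int

    @property
    def linkage_matrix(self) -> np.ndarray:
        counts = _merge_counts(self.merges, self.n)
        return np.column_stack(
            [self.merges.astype(float), self.heights, counts.astype(float)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, self.n),
                "cluster1": self.merges[:, 0],
                "cluster2": self.merges[:, 1],
                "coefficient": self.coefficients,
            }
        )


def _merge_counts(merges: np.ndarray, n: int) -> np.ndarray:
    sizes = {i: 1 for i in range(n)}
    counts = np.empty(len(merges), dtype=int)
    for k, (a, b) in enumerate(merges):
        c = sizes[int(a)] + sizes[int(b)]
        sizes[n + k] = c
        counts[k] = c
    return counts


def ward_linkage(X: np.ndarray, zscore: bool = False) -> AgglomerationSchedule:
    """Agglomeration schedule of Ward clustering on a feature matrix.

    Coefficients are cumulative total within-cluster SS: each merge adds
    h^2/2, where h is the Ward merge height on raw Euclidean distances, so the
    last coefficient equals the total SS of the data about its mean.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    bad = np.where(~np.all(np.isfinite(X), axis=1))[0]
    if len(bad):
        raise ValueError(f"rows with missing values: {bad.tolist()}")
    if zscore:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method="ward")
    heights = Z[:, 2]
    coefficients = np.cumsum(heights**2 / 2.0)
    return AgglomerationSchedule(
        merges=Z[:, :2].astype(int), heights=heights,
        coefficients=coefficients, n=X.shape[0],
    )


@dataclass(frozen=True)
class KSelection:
    k: int
    ratios: dict[int, float]  # candidate k -> relative coefficient jump
    confident: bool

    def __int__(self) -> int:
        return self.k


def select_k(
    schedule: AgglomerationSchedule, k_max: int = 10, *, min_ratio: float = 1.8
) -> KSelection:
    """Choose the cluster count at the schedule's elbow.

    For each candidate k, the merge that reduces k clusters to k - 1 is
    step n - k + 1; how much that merge costs relative to the one before
    it is the jump ratio (ratio of successive coefficient increments).
    Once genuinely distinct clusters start merging, every later merge is
    also expensive, so real structure at k clusters shows a *sustained*
    run of marked jumps from k down to 2 — an isolated noise jump does
    not.  The chosen k is therefore the largest candidate whose jump
    ratios reach ``min_ratio`` at every step from k down to 2.  When no
    candidate qualifies (e.g. uniform data, which need not have an elbow)
    the argmax ratio is returned with a low-confidence flag.
    """
    n = schedule.n
    if not (1 < k_max < n):
        raise ValueError("k_max must lie in (1, n)")
    c = schedule.coefficients
    inc = np.diff(c, prepend=0.0)
    ratios = {}
    for k in range(2, k_max + 1):
        step = n - k + 1  # 1-based step index of the merge going k -> k-1
        prev = inc[step - 2] if step >= 2 else np.nan
        ratios[k] = float(inc[step - 1] / prev) if prev and prev > 0 else np.inf
    qualifying = [
        k for k in ratios
        if all(ratios[j] >= min_ratio for j in range(2, k + 1))
    ]
    if qualifying:
        return KSelection(k=max(qualifying), ratios=ratios, confident=True)
    k_best = max(ratios, key=lambda k: (ratios[k], k))
    return KSelection(k=k_best, ratios=ratios, confident=False)


def cut_tree(schedule: AgglomerationSchedule, k: int) -> np.ndarray:
    """Membership labels 1..k consistent with the merge order."""
    if not (1 <= k <= schedule.n):
        raise ValueError("k must lie in [1, n]")
    if k == schedule.n:
        return np.arange(1, schedule.n + 1)
    labels = hierarchy.fcluster(schedule.linkage_matrix, t=k, criterion="maxclust")
    return labels.astype(int)


def cluster_parameters(
    X: np.ndarray, k_max: int = 10, zscore: bool = False
) -> tuple[np.ndarray, KSelection, AgglomerationSchedule]:
    """Convenience: schedule + k selection + membership in one call."""
    schedule = ward_linkage(X, zscore=zscore)
    sel = select_k(schedule, k_max=min(k_max, schedule.n - 1))
    return cut_tree(schedule, sel.k), sel, schedule
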
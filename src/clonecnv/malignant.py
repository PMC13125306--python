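"""Tumor-cell classification: 1-D k-means over per-cell CNV scores (k = 3);
the cluster with the highest mean score is labelled tumor, everything else
unassigned."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["kmeans1d", "label_tumor", "MalignancyCall"]


@dataclass
class MalignancyCall:
    cluster: pd.Series  # cell id -> cluster index
    label: pd.Series  # cell id -> "tumor" | "unassigned"
    cluster_means: np.ndarray
    cluster_sizes: np.ndarray
    tumor_cluster: int


def kmeans1d(scores, k: int = 3, seed: int = 0) -> np.ndarray:
    """Exact 1-D k-means.

    Optimal 1-D clusters are contiguous in sorted order, so the globally
    optimal partition is found by dynamic programming over split points
    (O(k n^2) with prefix sums); this is deterministic and always attains the
    minimum within-cluster sum of squares, which Lloyd iterations from
    quantile seeds only approximate. ``seed`` is accepted for interface
    symmetry but unused. Ties in assignment go to the lower cluster index by
    construction (stable sorted order).
    """
    x = np.asarray(scores, dtype=float)
    if len(np.unique(x)) < k:
        raise ValueError(
            f"need at least {k} distinct score values for k={k}, "
            f"got {len(np.unique(x))}"
        )
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(xs)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def sse(i, j):  # cost of one cluster covering xs[i:j]
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / (j - i)

    # dp[m][j] = optimal cost of splitting xs[:j] into m clusters
    dp = np.full((k + 1, n + 1), np.inf)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, best_i = np.inf, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1, i] + sse(i, j)
                if c < best - 1e-15:
                    best, best_i = c, i
            dp[m, j] = best
            arg[m, j] = best_i
    # backtrack split points
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = arg[m, j]
        bounds.append(j)
    bounds = bounds[::-1]
    assignment = np.empty(n, dtype=int)
    for m in range(k):
        assignment[order[bounds[m]:bounds[m + 1]]] = m
    return assignment


def kmeans1d_objective(scores, assignment) -> float:
    x = np.asarray(scores, dtype=float)
    total = 0.0
    for c in np.unique(assignment):
        v = x[assignment == c]
        total += float(((v - v.mean()) ** 2).sum())
    return total


def label_tumor(assignment, scores, cell_ids=None) -> MalignancyCall:
    """Label the cluster with the maximal mean score as tumor, the rest as
    unassigned. A tie between cluster means (within 1e-12) is an error
    demanding manual review."""
    scores = np.asarray(scores, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(len(scores))]
    clusters = np.unique(assignment)
    means = np.array([scores[assignment == c].mean() for c in clusters])
    sizes = np.array([(assignment == c).sum() for c in clusters])
    top = np.max(means)
    winners = clusters[means >= top - 1e-12]
    if len(winners) > 1:
        raise ValueError(
            f"clusters {list(winners)} tie on mean score ({top:.6g}); manual review required"
        )
    tumor = int(winners[0])
    labels = np.where(assignment == tumor, "tumor", "unassigned")
    idx = pd.Index(cell_ids)
    return MalignancyCall(
        cluster=pd.Series(assignment, index=idx, name="cluster"),
        label=pd.Series(labels, index=idx, name="label"),
        cluster_means=means,
        cluster_sizes=sizes,
        tumor_cluster=tumor,
    )
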
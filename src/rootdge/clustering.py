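"""Hierarchical clustering of salinity-response profiles.

Genes are clustered on their log2(treatment/control) profiles across the
three root-type comparisons using Euclidean distance and complete-linkage
agglomeration (inter-cluster distance = maximum pairwise member distance).
Cells where a gene had no expression in at least one sample of a comparison
are missing ("gray"): distances are computed over shared observed positions,
and under the default policy genes with any missing value are carried in the
reordered output, gray-masked, but excluded from the dendrogram.

The agglomeration is implemented here rather than delegated, because the
leaf order is pinned down by a deterministic tie-break (lowest pair of
cluster indices) that generic linkage routines do not guarantee. Merge
indices follow the usual convention: leaves are 0..n-1, the cluster formed
by merge i is n+i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "Dendrogram",
    "euclidean_distance",
    "complete_linkage",
    "cluster_profiles",
    "read_profiles",
    "write_dendrogram",
]


@dataclass(frozen=True)
class ProfileMatrix:
    """Genes x comparisons matrix of log2 ratios; NaN marks missing cells."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("comparison labels must be unique")
        with np.errstate(invalid="ignore"):
            finite = np.isfinite(self.values.to_numpy(dtype=float))
        missing = self.values.isna().to_numpy()
        if not (finite | missing).all():
            raise ValueError("profile values must be finite where not missing")

    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: ordered merge list and the induced leaf order."""

    n_leaves: int
    merges: tuple[tuple[int, int, float], ...]  # (member_a, member_b, height)
    leaf_order: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != max(self.n_leaves - 1, 0):
            raise ValueError("a dendrogram over n leaves has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("complete-linkage merge heights must be non-decreasing")


def euclidean_distance(profile_a, profile_b) -> float:
    """Euclidean distance over positions observed in both profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    shared = ~(np.isnan(a) | np.isnan(b))
    if not shared.any():
        raise ValueError("profiles share no observed positions")
    d = a[shared] - b[shared]
    return float(np.sqrt(np.sum(d * d)))


def complete_linkage(distance_matrix) -> Dendrogram:
    """Agglomerate with complete linkage and lowest-index tie-breaking."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    # active clusters: id -> index into the working distance matrix
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    active = sorted(members)
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        merges.append((a, b, h))
        children[next_id] = (a, b)
        members[next_id] = members[a] + members[b]
        active = [c for c in active if c not in (a, b)]
        new_dists = {}
        for c in active:
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            new_dists[(c, next_id)] = max(da, db)
        dist.pop((a, b))
        dist.update(new_dists)
        active.append(next_id)
        next_id += 1

    def _order(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return _order(left) + _order(right)

    leaf_order = tuple(_order(next_id - 1)) if n > 1 else tuple(range(n))
    return Dendrogram(n_leaves=n, merges=tuple(merges), leaf_order=leaf_order)


def _pairwise_distances(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = euclidean_distance(values[i], values[j])
    return D


def cluster_profiles(
    matrix: ProfileMatrix, policy: str = "complete-rows"
) -> tuple[Dendrogram, pd.DataFrame, pd.DataFrame]:
    """Cluster gene profiles; returns (dendrogram, reordered matrix, gray mask).

    policy "complete-rows" (default): genes with any missing value are
    excluded from distance computation and appended, gray-masked, after the
    ordered leaves. policy "pairwise": distances use pairwise-complete
    positions, so partially observed genes are clustered too; genes sharing
    no observed position with the rest are excluded and appended.
    """
    if policy not in ("complete-rows", "pairwise"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    vals = matrix.values
    if matrix.missing.all(axis=1).all():
        raise ValueError("all rows are fully missing")
    if policy == "complete-rows":
        usable = ~matrix.missing.any(axis=1)
    else:
        usable = ~matrix.missing.all(axis=1)
        arr = vals.to_numpy(dtype=float)
        idx = list(np.flatnonzero(usable.to_numpy()))
        # drop rows until every remaining pair shares an observed position
        while True:
            bad_counts = {i: 0 for i in idx}
            for ii, i in enumerate(idx):
                for j in idx[ii + 1 :]:
                    if not (~(np.isnan(arr[i]) | np.isnan(arr[j]))).any():
                        bad_counts[i] += 1
                        bad_counts[j] += 1
            worst = max(bad_counts, key=lambda k: (bad_counts[k], k))
            if bad_counts[worst] == 0:
                break
            idx.remove(worst)
        keep = np.zeros(len(vals), dtype=bool)
        keep[idx] = True
        usable = pd.Series(keep, index=vals.index)
    used = vals.loc[usable]
    if len(used) < 2:
        raise ValueError("need at least 2 clusterable gene profiles")
    D = _pairwise_distances(used.to_numpy(dtype=float))
    dendro = complete_linkage(D)
    ordered = used.iloc[list(dendro.leaf_order)]
    grayed = vals.loc[~usable]
    out = pd.concat([ordered, grayed])
    return dendro, out, out.isna()


# -- TSV I/O ------------------------------------------------------------------


def read_profiles(path: str | Path) -> ProfileMatrix:
    """Profile TSV: gene id column then one log2-ratio column per comparison;
    empty cells are missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProfileMatrix(values=df)


def write_dendrogram(dendro: Dendrogram, path: str | Path) -> None:
    df = pd.DataFrame(dendro.merges, columns=["member_a", "member_b", "height"])
    df.to_csv(path, sep="\t", index=False)
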
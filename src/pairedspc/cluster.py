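"""Two-way agglomerative clustering of fold-change profiles.

Pearson distance (1 - r) plus Ward's minimum-variance aggregation, the
combination used for secretome heatmaps. ``ward_cluster`` is a greedy
Lance-Williams implementation operating on the input dissimilarities in
squared-distance semantics (1 - r of z-scored rows is, up to a constant,
a squared Euclidean distance), with a deterministic lexicographic
tie-break so dendrograms are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dendrogram", "pearson_distance", "ward_cluster", "two_way_cluster"]


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage convention.

    ``linkage`` rows are (cluster_i, cluster_j, height, size) with original
    leaves labelled 0..n-1 and the k-th merge creating cluster n+k;
    ``leaf_order`` is the displayed leaf permutation, where each merge
    places the subtree containing the smaller minimal original index first.
    """

    linkage: np.ndarray
    n_leaves: int
    leaf_order: list[int]
    labels: list[str] | None = None

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_pairs(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in self.linkage[:, :2]]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        labels = self.labels or [str(i) for i in range(self.n_leaves)]
        if self.n_leaves == 1:
            return f"{labels[0]};"
        height = {i: 0.0 for i in range(self.n_leaves)}
        node: dict[int, str] = {i: labels[i] for i in range(self.n_leaves)}
        minleaf = {i: i for i in range(self.n_leaves)}
        for k, (i, j, h, _size) in enumerate(self.linkage):
            i, j = int(i), int(j)
            a, b = (i, j) if minleaf[i] <= minleaf[j] else (j, i)
            bl_a = max(h - height[a], 0.0)
            bl_b = max(h - height[b], 0.0)
            new = self.n_leaves + k
            node[new] = f"({node[a]}:{bl_a:.10g},{node[b]}:{bl_b:.10g})"
            height[new] = float(h)
            minleaf[new] = min(minleaf[a], minleaf[b])
        return node[self.n_leaves + len(self.linkage) - 1] + ";"


def pearson_distance(x, axis: str = "rows") -> np.ndarray:
    """Pairwise Pearson distance d = 1 - r between rows or columns.

    Raises on zero-variance vectors (they have no defined correlation and
    are pre-filtered upstream). The result is clipped to [0, 2] with a
    zero diagonal.
    """
    df = pd.DataFrame(x)
    if axis == "columns":
        df = df.T
    elif axis != "rows":
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least two vectors of length >= 2")
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = [str(df.index[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance vector(s): {bad}")
    r = np.corrcoef(vals)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def ward_cluster(d: np.ndarray) -> Dendrogram:
    """Agglomerative Ward clustering of a dissimilarity matrix.

    The input is treated as squared-distance-scale dissimilarities (as
    1 - r is). At each step the pair of clusters with the minimal Ward
    dissimilarity merges; ties break on the lexicographically smallest
    (cluster_i, cluster_j) label pair, labels assigned in creation order.
    Inter-cluster dissimilarities update by the Lance-Williams recurrence
    for Ward's criterion, so merge heights are monotone non-decreasing.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    if n == 1:
        return Dendrogram(np.empty((0, 4)), 1, [0])
    big = np.inf
    work = d.copy()
    np.fill_diagonal(work, big)
    active = np.ones(n * 2 - 1, dtype=bool)
    active[n:] = False
    sizes = np.ones(2 * n - 1)
    # work grows to hold merged clusters at positions n..2n-2; position
    # order equals label creation order, so row-major argmin realizes the
    # lexicographic tie-break.
    full = np.full((2 * n - 1, 2 * n - 1), big)
    full[:n, :n] = work
    linkage = np.zeros((n - 1, 4))
    members: list[list[int]] = [[i] for i in range(n)] + [[] for _ in range(n - 1)]
    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = full[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        flat = sub[iu]
        best = int(np.argmin(flat))  # first minimum = lexicographically smallest pair
        i, j = int(idx[iu[0][best]]), int(idx[iu[1][best]])
        h = full[i, j]
        new = n + step
        linkage[step] = (i, j, h, sizes[i] + sizes[j])
        members[new] = members[i] + members[j]
        # Lance-Williams (Ward) update against every other active cluster
        others = idx[(idx != i) & (idx != j)]
        if others.size:
            ni, nj, nk = sizes[i], sizes[j], sizes[others]
            tot = ni + nj + nk
            upd = ((ni + nk) * full[i, others] + (nj + nk) * full[j, others] - nk * h) / tot
            full[new, others] = upd
            full[others, new] = upd
        active[i] = active[j] = False
        active[new] = True
        sizes[new] = sizes[i] + sizes[j]
    order = _leaf_order(linkage, n)
    return Dendrogram(linkage, n, order)


def _leaf_order(linkage: np.ndarray, n: int) -> list[int]:
    minleaf: dict[int, int] = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (i, j, _h, _s) in enumerate(linkage):
        i, j = int(i), int(j)
        node = n + k
        children[node] = (i, j)
        minleaf[node] = min(minleaf[i], minleaf[j])

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        i, j = children[node]
        first, second = (i, j) if minleaf[i] <= minleaf[j] else (j, i)
        return walk(first) + walk(second)

    return walk(n + len(linkage) - 1)


def two_way_cluster(x: pd.DataFrame) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Cluster rows and columns independently; reorder the matrix by both.

    Rows (typically proteins) and columns (conditions) each get a
    Pearson-distance Ward dendrogram. Single-row or single-column matrices
    get a trivial dendrogram on that axis.
    """
    x = pd.DataFrame(x)
    if x.shape[0] > 1:
        row_dend = ward_cluster(pearson_distance(x, axis="rows"))
    else:
        row_dend = Dendrogram(np.empty((0, 4)), 1, [0])
    if x.shape[1] > 1:
        if x.shape[0] > 1:
            col_d = pearson_distance(x, axis="columns")
        else:
            # length-1 column vectors have no correlation; fall back to
            # squared value differences so columns still cluster
            v = x.to_numpy(dtype=float).ravel()
            col_d = (v[:, None] - v[None, :]) ** 2
        col_dend = ward_cluster(col_d)
    else:
        col_dend = Dendrogram(np.empty((0, 4)), 1, [0])
    row_dend.labels = [str(i) for i in x.index]
    col_dend.labels = [str(c) for c in x.columns]
    reordered = x.iloc[row_dend.leaf_order, col_dend.leaf_order]
    return row_dend, col_dend, reordered
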
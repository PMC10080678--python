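"""Hierarchical clustering of concentration time traces.

Pairwise distances are the correlation distance

    d(u, v) = 1 - ((u - mean(u)) . (v - mean(v)))
                  / (||u - mean(u)||_2 * ||v - mean(v)||_2)

which ranges from 0 (identical shape) to 2 (perfect anticorrelation).
Agglomeration uses average linkage with the proportional-average update

    d(A u B, Y) = (|A| d(A, Y) + |B| d(B, Y)) / (|A| + |B|)

and records each merge at height d(A, B) / 2 — note this is half the
conventional cophenetic height, kept deliberately for comparability
with the analysis convention this package implements.  Exact distance
ties are broken by the lowest pair of cluster indices in creation
order; correlation distance is non-metric, so height inversions are
possible and are reported rather than assumed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crn_sim import TraceSet

__all__ = [
    "ClusteringError",
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "correlation_distance",
    "pairwise_distances",
    "average_linkage",
    "cut_clusters",
]


class ClusteringError(ValueError):
    """Invalid traces or clustering parameters."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ClusteringError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ClusteringError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ClusteringError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12) or np.any(self.d > 2 + 1e-9):
            raise ClusteringError("correlation distances must lie in [0, 2]")


@dataclass
class Dendrogram:
    """Merge records in scipy-like encoding.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height,
    size); leaves are numbered 0..n-1 and merge i creates cluster n+i.
    Heights follow the d/2 convention.  ``inversions`` counts merges
    whose height is below a previous merge's height.
    """

    merges: np.ndarray
    leaf_labels: list[str]
    inversions: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix with conventional full heights (2x the d/2 heights)."""
        z = self.merges.copy()
        z[:, 2] *= 2.0
        return z

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram display order (left-to-right)."""
        order: list[int] = []

        def walk(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = self.merges[node - self.n_leaves, :2]
                walk(int(a))
                walk(int(b))

        walk(self.n_leaves + len(self.merges) - 1)
        return [self.leaf_labels[i] for i in order]


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]
    cut_parameter: tuple[str, float]  # ("k", k) or ("height", h)

    def labels_for(self, ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids])


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Correlation distance between two equal-length traces."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ClusteringError("traces must be 1-D and of equal length")
    if u.size < 3:
        raise ClusteringError("traces must have length >= 3")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise ClusteringError("correlation distance undefined for a constant trace")
    return float(1.0 - (uc @ vc) / (nu * nv))


def pairwise_distances(traces: TraceSet) -> DistanceMatrix:
    """Correlation-distance matrix over all compound pairs."""
    if traces.n_compounds < 2:
        raise ClusteringError("need at least two compounds")
    x = traces.concentrations
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = [cid for cid, nrm in zip(traces.compound_ids, norms) if nrm == 0.0]
    if constant:
        raise ClusteringError(
            f"constant traces have no defined correlation distance: {constant}"
        )
    r = (centered @ centered.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=list(traces.compound_ids), d=d)


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA with the proportional-average update and d/2 merge heights."""
    n = len(dm.labels)
    if n < 2:
        raise ClusteringError("need at least two leaves")
    # active clusters keyed by creation-order id; distances in a dict-of-dict
    size = {i: 1 for i in range(n)}
    dist = {
        (i, j): dm.d[i, j]
        for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    inversions = 0
    prev_height = -np.inf
    next_id = n
    for step in range(n - 1):
        # closest pair; ties broken by lowest (i, j) in creation order
        best = min(
            ((dist[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        d_ab, (a, b) = best
        height = d_ab / 2.0
        if height < prev_height - 1e-15:
            inversions += 1
        prev_height = max(prev_height, height)
        merges[step] = (a, b, height, size[a] + size[b])
        for y in active:
            if y in (a, b):
                continue
            day = dist[(min(a, y), max(a, y))]
            dby = dist[(min(b, y), max(b, y))]
            dist[(min(next_id, y), max(next_id, y))] = (
                size[a] * day + size[b] * dby
            ) / (size[a] + size[b])
        size[next_id] = size[a] + size[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(merges=merges, leaf_labels=list(dm.labels),
                      inversions=inversions)


def cut_clusters(
    dend: Dendrogram,
    k: int | None = None,
    height: float | None = None,
) -> ClusterAssignment:
    """Flat partition by merge truncation (``k`` clusters) or height threshold.

    With ``k``, the first ``n - k`` merges (in merge order) are applied.
    With ``height``, every merge whose height is at or below the
    threshold is applied, in merge order.
    """
    n = dend.n_leaves
    if (k is None) == (height is None):
        raise ClusteringError("specify exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ClusteringError(f"k must be in [1, {n}]")
        applied = range(n - k)
        param = ("k", float(k))
    else:
        applied = [i for i, h in enumerate(dend.merges[:, 2]) if h <= height]
        param = ("height", float(height))

    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in applied:
        a, b = int(dend.merges[i, 0]), int(dend.merges[i, 1])
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node

    roots: dict[int, int] = {}
    assignment = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[dend.leaf_labels[leaf]] = roots[r]
    return ClusterAssignment(assignment=assignment, cut_parameter=param)
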
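"""Distance-threshold neighbor graphs over soma clouds.

Two soma are *adjacent* when their Euclidean 3D distance is at most a
threshold (0.17 nad reproduces the in vivo mean subcluster size of ~7
cells).  Each cell defines one *subcluster*: the focal cell plus all of
its neighbors.  Subclusters overlap; they are not a partition.  The mean
subcluster size equals the mean degree plus one and is the quantity the
generator is calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from dcnsim.synthetic_cluster import SomaCloud

__all__ = [
    "NeighborGraph",
    "Subcluster",
    "pairwise_distances",
    "build_graph",
    "subclusters",
    "mean_subcluster_size",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric boolean adjacency induced by a distance threshold.

    ``degree[i]`` is the neighbor count of cell *i* -- the ``r`` of the
    trans-Delta averaging rule ``dl_i = (1/r_i) sum_j Dl_j``.
    """

    threshold: float
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diagonal(adj)):
            raise ValueError("self-adjacency is not allowed")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def connected_components(self) -> list[np.ndarray]:
        """Index arrays of connected components (BFS over adjacency)."""
        n = self.n_cells
        seen = np.zeros(n, dtype=bool)
        out: list[np.ndarray] = []
        for start in range(n):
            if seen[start]:
                continue
            frontier = [start]
            seen[start] = True
            members = [start]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in np.flatnonzero(self.adjacency[u]):
                        if not seen[v]:
                            seen[v] = True
                            members.append(int(v))
                            nxt.append(int(v))
                frontier = nxt
            out.append(np.array(sorted(members), dtype=int))
        return out


@dataclass(frozen=True)
class Subcluster:
    """A focal cell together with all of its threshold neighbors."""

    focal: int
    members: np.ndarray

    def __post_init__(self) -> None:
        members = np.asarray(self.members, dtype=int)
        if self.focal not in members:
            raise ValueError("focal cell must be a member of its subcluster")
        members.setflags(write=False)
        object.__setattr__(self, "members", members)

    @property
    def size(self) -> int:
        return len(self.members)


def pairwise_distances(cloud: SomaCloud) -> np.ndarray:
    """Symmetric Euclidean 3D distance matrix in nad (zero diagonal)."""
    if not np.all(np.isfinite(cloud.points)):
        raise ValueError("cloud contains non-finite coordinates")
    if cloud.n_cells == 1:
        return np.zeros((1, 1))
    return squareform(pdist(cloud.points, metric="euclidean"))


def build_graph(cloud: SomaCloud, threshold: float) -> NeighborGraph:
    """Adjacency: ``i != j`` adjacent iff ``distance(i, j) <= threshold``.

    The boundary is inclusive, so a pair exactly at the threshold counts
    as adjacent while threshold 0 still leaves every cell isolated
    (distinct points have positive distance).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    dist = pairwise_distances(cloud)
    adj = dist <= threshold
    np.fill_diagonal(adj, False)
    return NeighborGraph(threshold=float(threshold), adjacency=adj)


def subclusters(graph: NeighborGraph) -> list[Subcluster]:
    """One overlapping subcluster per cell: ``{i} | neighbors(i)``."""
    out = []
    for i in range(graph.n_cells):
        members = np.concatenate([[i], graph.neighbors(i)])
        out.append(Subcluster(focal=i, members=np.sort(members)))
    return out


def mean_subcluster_size(
    cohort: list[SomaCloud] | SomaCloud, threshold: float
) -> float:
    """Grand mean subcluster size over all cells of all clouds."""
    clouds = [cohort] if isinstance(cohort, SomaCloud) else list(cohort)
    if not clouds:
        raise ValueError("cohort must be non-empty")
    sizes: list[np.ndarray] = []
    for cloud in clouds:
        graph = build_graph(cloud, threshold)
        sizes.append(graph.degree + 1)
    return float(np.mean(np.concatenate(sizes)))
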
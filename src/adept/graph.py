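"""Spatial kNN graph over spot coordinates.

Spots have no explicit edge relationships, so adjacency is built with
k-nearest neighbors on the 2-D coordinates (k=6 by default, matching the
hexagonal packing of Visium arrays).  Every node carries a self-loop because
the attention aggregation includes the node itself in its neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpatialGraph", "build_knn_graph"]


@dataclass
class SpatialGraph:
    """Directed edge list over spots; edge (u, v) means v is a neighbor of u.

    ``neighbors(u)`` (the in-neighborhood N_u) always contains u itself.
    """

    n_nodes: int
    edges: np.ndarray  # (n_edges, 2) int, rows (u, v)
    k: int
    _nbr: list[np.ndarray] = field(default=None, repr=False, compare=False)
    _csr: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64)
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be an (n, 2) array")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        present = np.zeros(self.n_nodes, dtype=bool)
        loops = self.edges[:, 0] == self.edges[:, 1]
        present[self.edges[loops, 0]] = True
        if not present.all():
            raise ValueError("every node needs a self-loop")
        # canonical lexicographic edge order; csr_template relies on it
        self.edges = self.edges[np.lexsort((self.edges[:, 1], self.edges[:, 0]))]

    def csr_template(self):
        """(indptr, indices) of the adjacency in CSR layout.

        Valid because edges are stored lexicographically sorted by (u, v);
        per-edge values laid out in edge order drop straight into
        ``scipy.sparse.csr_matrix((values, indices, indptr))``.
        """
        if self._csr is None:
            src, dst = self.edges[:, 0], self.edges[:, 1]
            indptr = np.searchsorted(src, np.arange(self.n_nodes + 1)).astype(np.int32)
            self._csr = (indptr, dst.astype(np.int32))
        return self._csr

    def neighbor_lists(self) -> list[np.ndarray]:
        """Sorted neighbor array per node (cached)."""
        if self._nbr is None:
            order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
            e = self.edges[order]
            splits = np.searchsorted(e[:, 0], np.arange(1, self.n_nodes))
            self._nbr = [np.unique(a[:, 1]) for a in np.split(e, splits)]
        return self._nbr

    def neighbors(self, u: int) -> np.ndarray:
        return self.neighbor_lists()[u]

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t", header="u\tv", comments="")


def build_knn_graph(coords: np.ndarray, k: int = 6, symmetrize: bool = True) -> SpatialGraph:
    """Build the spot adjacency graph from coordinates via Euclidean kNN.

    Each spot is connected to its ``k`` nearest neighbors plus itself.
    Distance ties are broken by smaller node index so the graph is a
    deterministic function of the input.  With ``symmetrize`` (default) the
    union with the reversed edges is returned, so neighborhoods are mutual.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")
    # Exact pairwise distances in chunks: spot counts are a few thousand at
    # most, and this makes the (distance, index) tie-break deterministic,
    # which sklearn's kneighbors does not guarantee under ties.
    idx_all = np.arange(n)
    edges = []
    chunk = max(1, min(n, 2_000_000 // max(n, 1)))
    for start in range(0, n, chunk):
        rows = slice(start, min(start + chunk, n))
        d2 = ((coords[rows, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        for i, u in enumerate(range(rows.start, rows.stop)):
            order = np.lexsort((idx_all, d2[i]))
            nearest = [v for v in order if v != u][:k]
            for v in sorted(set(nearest) | {u}):
                edges.append((u, v))
    edges = np.asarray(edges, dtype=np.int64)
    if symmetrize:
        rev = edges[:, ::-1]
        edges = np.unique(np.vstack([edges, rev]), axis=0)
    return SpatialGraph(n_nodes=n, edges=edges, k=k)
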
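"""Spatial neighbourhood graphs.

A :class:`SpatialGraph` holds a binary symmetric KNN adjacency built from
spot coordinates, its undirected edge list, and the symmetrically normalised
operator ``A_hat = D^{-1/2} A D^{-1/2}`` used by the graph-convolutional
encoder.  Self-loops are never added: the encoder must aggregate from
neighbours, which is what makes node masking informative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree


@dataclass
class SpatialGraph:
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal
    edges: np.ndarray  # (n_edges, 2) int array, each row (i, j) with i < j
    norm_operator: sp.csr_matrix  # D^{-1/2} A D^{-1/2}
    k: int

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def neighbor_sets(self) -> List[set]:
        """N(v_i) for every node, from the symmetric adjacency."""
        A = self.adjacency.tocsr()
        return [set(A.indices[A.indptr[i]: A.indptr[i + 1]]) for i in range(A.shape[0])]

    # -- persistence ------------------------------------------------------
    def save_edgelist(self, path) -> None:
        """Write the undirected edge list as TSV with a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"k": self.k, "n_spots": self.n_spots}))

    @classmethod
    def load_edgelist(cls, path) -> "SpatialGraph":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        edges = np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)
        n = meta["n_spots"]
        A = _adjacency_from_edges(edges, n)
        return cls(adjacency=A, edges=edges, norm_operator=_sym_normalize(A), k=meta["k"])


def _adjacency_from_edges(edges: np.ndarray, n: int) -> sp.csr_matrix:
    if edges.size == 0:
        return sp.csr_matrix((n, n))
    i, j = edges[:, 0], edges[:, 1]
    data = np.ones(2 * len(i))
    A = sp.coo_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))
    A = A.tocsr()
    A.data[:] = 1.0  # collapse duplicates to binary
    return A


def _sym_normalize(A: sp.spmatrix) -> sp.csr_matrix:
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(deg)
    inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0  # isolated nodes stay all-zero
    D = sp.diags(inv_sqrt)
    return (D @ A @ D).tocsr()


def _knn_edges(coords: np.ndarray, k: int) -> np.ndarray:
    """Directed KNN picks (self excluded), ties broken by smaller node index.

    Returns the symmetrised (union) undirected edge array with i < j rows.
    """
    n = coords.shape[0]
    tree = cKDTree(coords)
    # query k+1 (self comes back at distance 0); duplicate coordinates mean
    # self is not guaranteed first, so drop it explicitly.
    dist, idx = tree.query(coords, k=min(k + 1, n))
    pairs = set()
    order_keys = None
    for i in range(n):
        di, ii = dist[i], idx[i]
        mask = ii != i
        di, ii = di[mask], ii[mask]
        # stable tie-break: sort by (distance, index)
        order = np.lexsort((ii, di))
        chosen = ii[order][:k]
        for j in chosen:
            pairs.add((min(i, int(j)), max(i, int(j))))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(pairs), dtype=int)


def build_knn_graph(coords: np.ndarray, k: int = 6) -> SpatialGraph:
    """Union-symmetrised K-nearest-neighbour graph on Euclidean coordinates.

    Each node points at its ``k`` nearest neighbours (self excluded; exact
    distance ties resolved toward the smaller node index) and an undirected
    edge exists when either endpoint selected the other.  ``k`` is clipped
    to ``n_spots - 1`` with a warning when it is too large.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to build a graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        warnings.warn(f"k={k} >= n_spots={n}; clipping to {n - 1}")
        k = n - 1
    edges = _knn_edges(coords, k)
    A = _adjacency_from_edges(edges, n)
    return SpatialGraph(adjacency=A, edges=edges, norm_operator=_sym_normalize(A), k=k)


def normalize_adjacency(graph: SpatialGraph) -> SpatialGraph:
    """Recompute ``A_hat = D^{-1/2} A D^{-1/2}`` from the stored adjacency."""
    return SpatialGraph(
        adjacency=graph.adjacency,
        edges=graph.edges,
        norm_operator=_sym_normalize(graph.adjacency),
        k=graph.k,
    )


def graph_from_adjacency(A: sp.spmatrix, k: int = 0) -> SpatialGraph:
    """Wrap an existing binary symmetric adjacency (used by masking)."""
    A = sp.csr_matrix(A)
    coo = sp.triu(A, k=1).tocoo()
    edges = (
        np.column_stack([coo.row, coo.col]).astype(int)
        if coo.nnz
        else np.empty((0, 2), dtype=int)
    )
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))] if edges.size else edges
    return SpatialGraph(adjacency=A, edges=edges, norm_operator=_sym_normalize(A), k=k)


def median_nn_distance(coords: np.ndarray) -> float:
    """Median nearest-neighbour distance within a slice (default z spacing)."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    return float(np.median(dist[:, 1]))


def build_3d_graph(
    slices: Sequence, z_gap: Optional[float] = None, k: int = 6
) -> Tuple[SpatialGraph, np.ndarray]:
    """KNN graph over spots of several aligned slices stacked along z.

    Slice ``s`` is placed at ``z = s * z_gap``; a single KNN graph is then
    built on the stacked (x, y, z) coordinates, so edges may cross slices.
    ``z_gap`` defaults to the median within-slice nearest-neighbour spacing
    of the first slice.  Accepts either coordinate arrays or objects with a
    ``coords`` attribute.  Returns the graph and the per-spot slice index.
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices")
    coord_list = [np.asarray(getattr(s, "coords", s), dtype=float) for s in slices]
    if z_gap is None:
        z_gap = median_nn_distance(coord_list[0])
    if z_gap <= 0:
        raise ValueError("z_gap must be positive")
    stacked = np.vstack(
        [np.column_stack([c[:, :2], np.full(len(c), s * z_gap)]) for s, c in enumerate(coord_list)]
    )
    slice_idx = np.concatenate(
        [np.full(len(c), s, dtype=int) for s, c in enumerate(coord_list)]
    )
    return build_knn_graph(stacked, k=k), slice_idx
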
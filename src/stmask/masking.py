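"""Dual-masking augmentation: node (feature) masking and edge masking.

Node masking hides a random fraction of spots' expression rows behind a
mask token, forcing the encoder to reconstruct them from spatial
neighbours.  Edge masking hides a random fraction of the undirected spatial
edges; the hidden edges become the positive pairs of the contrastive
channel.  Both draws are seeded and re-sampled every training epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .graph import SpatialGraph, _adjacency_from_edges, _sym_normalize, graph_from_adjacency


@dataclass
class MaskPlan:
    """One epoch's masking draw."""

    node_mask_rate: float
    edge_mask_rate: float
    masked_nodes: np.ndarray  # indices into V, |Vm| = floor(rate * N)
    masked_edges: np.ndarray  # (m, 2) undirected pairs drawn from E
    seed: Optional[int] = None


def mask_nodes(
    X: np.ndarray,
    rate: float,
    mask_token: np.ndarray,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Replace ``floor(rate * N)`` uniformly chosen rows of X by the token.

    Returns ``(X_masked, masked_index_array)``.  Unmasked rows are bitwise
    identical to the input.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("node mask rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = X.shape[0]
    m = int(np.floor(rate * n))
    vm = np.sort(rng.permutation(n)[:m])
    Xm = X.copy()
    if m:
        Xm[vm] = np.asarray(mask_token, dtype=X.dtype)
    return Xm, vm


def mask_edges(
    graph: SpatialGraph,
    rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SpatialGraph, np.ndarray]:
    """Drop each undirected edge independently with probability ``rate``.

    Both directions of a dropped edge are removed together, so the masked
    adjacency stays symmetric.  Returns the masked graph (with its own
    normalised operator) and the dropped edge array.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("edge mask rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    E = graph.edges
    drop = rng.random(len(E)) < rate
    kept, dropped = E[~drop], E[drop]
    n = graph.n_spots
    Am = _adjacency_from_edges(kept, n)
    masked = SpatialGraph(
        adjacency=Am, edges=kept, norm_operator=_sym_normalize(Am), k=graph.k
    )
    return masked, dropped


def plan_masks(
    X: np.ndarray,
    graph: SpatialGraph,
    node_rate: float,
    edge_rate: float,
    mask_token: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, SpatialGraph, MaskPlan]:
    """Draw one epoch's node and edge masks with a shared generator."""
    Xm, vm = mask_nodes(X, node_rate, mask_token, rng=rng)
    masked_graph, dropped = mask_edges(graph, edge_rate, rng=rng)
    plan = MaskPlan(
        node_mask_rate=node_rate,
        edge_mask_rate=edge_rate,
        masked_nodes=vm,
        masked_edges=dropped,
    )
    return Xm, masked_graph, plan
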
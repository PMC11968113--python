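"""Training loop, inference, clustering and denoising.

Each epoch re-draws the dual masks, runs the feature-masking channel
(masked features + full graph -> remask -> decode -> scaled cosine error)
and the edge-masking channel (full features + masked graph -> edge
discriminator -> NCE), and takes one Adam step on the weighted objective
``(1 - lambda) * L_SCE + lambda * L_NCE``.  The encoder is one parameter
set shared by both channels.  Ablation variants rewire which channels run,
which sets are masked, and how positive / negative edge pairs are chosen.

Inference is unmasked: the shared encoder is applied to the full features
and graph with batch-norm in running-average mode.  Clustering follows the
standard read-out — top 30 principal components of the embedding, then
k-means with 10 restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import nn
from .data import SpotDataset
from .graph import SpatialGraph
from .masking import mask_edges, mask_nodes

VARIANTS = (
    "full",
    "one_channel_combine",
    "dual_no_mask",
    "dual_no_node_mask",
    "dual_no_edge_mask",
    "mgae_only_masked",
    "mgae_only_unmasked",
    "mgcl_only_masked",
    "mgcl_only_unmasked",
    "pos_sel_remain",
    "neg_sel_random",
)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 2e-4
    epochs: int = 1000
    lam: float = 0.7
    node_mask_rate: float = 0.3
    edge_mask_rate: float = 0.4
    gamma: float = 2.0
    seed: int = 0
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        for r in (self.node_mask_rate, self.edge_mask_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("mask rates must lie in [0, 1]")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ClusterResult:
    labels: np.ndarray
    n_clusters: int
    embedding_pcs: np.ndarray


def _variant_wiring(cfg: TrainConfig) -> Dict:
    """Map a variant name onto channel switches and masking rates."""
    v = cfg.variant
    w = {
        "use_mgae": True,
        "use_mgcl": True,
        "one_channel": False,
        "node_rate": cfg.node_mask_rate,
        "edge_rate": cfg.edge_mask_rate,
        "pos_from_remaining": False,
        "neg_random": False,
    }
    if v == "one_channel_combine":
        w["one_channel"] = True
    elif v == "dual_no_mask":
        w["node_rate"] = 0.0
        w["edge_rate"] = 0.0
    elif v == "dual_no_node_mask":
        w["node_rate"] = 0.0
    elif v == "dual_no_edge_mask":
        w["edge_rate"] = 0.0
    elif v == "mgae_only_masked":
        w["use_mgcl"] = False
    elif v == "mgae_only_unmasked":
        w["use_mgcl"] = False
        w["node_rate"] = 0.0
    elif v == "mgcl_only_masked":
        w["use_mgae"] = False
    elif v == "mgcl_only_unmasked":
        w["use_mgae"] = False
        w["edge_rate"] = 0.0
    elif v == "pos_sel_remain":
        w["pos_from_remaining"] = True
    elif v == "neg_sel_random":
        w["neg_random"] = True
    return w


def train(
    data: SpotDataset,
    graph: SpatialGraph,
    cfg: Optional[TrainConfig] = None,
    state: Optional[nn.ModelState] = None,
) -> Tuple[nn.ModelState, np.ndarray]:
    """Optimise the dual-masking objective; returns (state, loss_trace).

    ``loss_trace`` has one row per epoch: (total, L_SCE, L_NCE); a channel
    that does not run in the chosen variant records NaN.  Fully
    deterministic for a fixed seed on one device.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(data.features, dtype=nn.DTYPE)
    if X.shape[0] != graph.n_spots:
        raise ValueError("features and graph disagree on the number of spots")
    n = X.shape[0]
    if state is None:
        state = nn.init_model(X.shape[1], seed=cfg.seed)
    wiring = _variant_wiring(cfg)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(state.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    neighbor_sets = graph.neighbor_sets()
    A_hat = graph.norm_operator.astype(nn.DTYPE)
    all_nodes = np.arange(n)
    trace = np.full((cfg.epochs, 3), np.nan)

    # channel weights on the combined objective
    if wiring["use_mgae"] and wiring["use_mgcl"]:
        w_sce, w_nce = 1.0 - cfg.lam, cfg.lam
    else:
        w_sce = 1.0 if wiring["use_mgae"] else 0.0
        w_nce = 1.0 if wiring["use_mgcl"] else 0.0

    for epoch in range(cfg.epochs):
        grads = state.zero_grads()
        active = set()

        # -- draw this epoch's masks -----------------------------------
        if wiring["node_rate"] > 0:
            Xm, vm = mask_nodes(X, wiring["node_rate"], state.params["x_token"], rng=rng)
        else:
            Xm, vm = X, np.array([], dtype=int)
        if wiring["edge_rate"] > 0:
            masked_graph, dropped = mask_edges(graph, wiring["edge_rate"], rng=rng)
        else:
            masked_graph, dropped = graph, np.empty((0, 2), dtype=int)
        # reconstruction target set: masked nodes, or every node when the
        # variant disables node masking
        sce_set = vm if len(vm) else all_nodes
        # positive edges: masked edges; the remaining edges for the
        # pos_sel_remain variant; the whole edge set when edge masking is off
        if wiring["pos_from_remaining"]:
            pos = masked_graph.edges
        elif len(dropped):
            pos = dropped
        else:
            pos = graph.edges
        Am_hat = masked_graph.norm_operator.astype(nn.DTYPE)

        l_sce = l_nce = np.nan
        dZ = dH_nce = None
        cache_e1 = cache_e2 = cache_d = None

        if wiring["one_channel"]:
            # single shared pass on (masked features, masked graph)
            H, cache_e1 = nn.encode(Xm, Am_hat, state, training=True, return_cache=True)
            Ht = nn.remask(H, vm, state.params["h_token"])
            Z, cache_d = nn.decode(Ht, Am_hat, state, training=True, return_cache=True)
            l_sce, dZ = nn.sce_loss_grad(X, Z, sce_set, cfg.gamma)
            edge_sets = _edge_sets(pos, n, neighbor_sets, graph, wiring, rng)
            l_nce, dH_nce = nn.nce_loss_grad(H, edge_sets, state, grads)
        else:
            if wiring["use_mgae"]:
                H1, cache_e1 = nn.encode(Xm, A_hat, state, training=True, return_cache=True)
                Ht = nn.remask(H1, vm, state.params["h_token"])
                Z, cache_d = nn.decode(Ht, A_hat, state, training=True, return_cache=True)
                l_sce, dZ = nn.sce_loss_grad(X, Z, sce_set, cfg.gamma)
            if wiring["use_mgcl"]:
                H2, cache_e2 = nn.encode(X, Am_hat, state, training=True, return_cache=True)
                edge_sets = _edge_sets(pos, n, neighbor_sets, graph, wiring, rng)
                l_nce, dH_nce = nn.nce_loss_grad(H2, edge_sets, state, grads)

        total = (w_sce * (0.0 if np.isnan(l_sce) else l_sce)
                 + w_nce * (0.0 if np.isnan(l_nce) else l_nce))
        trace[epoch] = (total, l_sce, l_nce)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: total={total}, "
                f"sce={l_sce}, nce={l_nce}"
            )

        # -- backward ----------------------------------------------------
        active.update(nn.ModelState.ENCODER_KEYS)
        if w_nce > 0 and dH_nce is not None:
            active.update(nn.ModelState.DISC_KEYS)
            if w_nce != 1.0:
                # discriminator grads were accumulated unweighted
                for k in nn.ModelState.DISC_KEYS:
                    grads[k] *= w_nce
        dH_enc1 = None
        if w_sce > 0 and dZ is not None:
            active.update(nn.ModelState.DECODER_KEYS)
            dHt = nn.decode_backward(w_sce * dZ, cache_d, state, grads)
            if len(vm):
                grads["h_token"] += dHt[vm].sum(axis=0)
                active.add("h_token")
                dHt = dHt.copy()
                dHt[vm] = 0.0
            dH_enc1 = dHt

        if wiring["one_channel"]:
            dH = np.zeros_like(dH_nce if dH_nce is not None else dH_enc1)
            if dH_enc1 is not None:
                dH += dH_enc1
            if w_nce > 0 and dH_nce is not None:
                dH += w_nce * dH_nce
            dXin = nn.encode_backward(dH, cache_e1, state, grads)
            if len(vm) and w_sce > 0:
                grads["x_token"] += dXin[vm].sum(axis=0)
                active.add("x_token")
        else:
            if dH_enc1 is not None:
                dXin = nn.encode_backward(dH_enc1, cache_e1, state, grads)
                if len(vm):
                    grads["x_token"] += dXin[vm].sum(axis=0)
                    active.add("x_token")
            if w_nce > 0 and dH_nce is not None:
                nn.encode_backward(w_nce * dH_nce, cache_e2, state, grads)

        opt.step(state.params, {k: grads[k] for k in active})

    state.dims["trained_epochs"] = int(state.dims.get("trained_epochs", 0)) + cfg.epochs
    return state, trace


def _edge_sets(pos, n, neighbor_sets, graph, wiring, rng) -> nn.EdgeSets:
    pos = np.asarray(pos).reshape(-1, 2)
    if len(pos) == 0:
        raise ValueError(
            "empty positive edge set: this variant requires edges to contrast"
        )
    counts = np.bincount(pos.ravel(), minlength=n)
    if wiring["neg_random"]:
        neg = nn.sample_random_negative_edges(2 * len(pos), n, graph.adjacency, rng)
    else:
        neg = nn.sample_negative_edges(pos, n, neighbor_sets, rng=rng)
    return nn.EdgeSets(pos=pos, neg=neg, per_node_counts=counts)


def embed(data: SpotDataset, graph: SpatialGraph, state: nn.ModelState) -> np.ndarray:
    """Inference embedding: shared encoder on the full features and graph,
    no masking, batch norm in running-average mode."""
    if int(state.dims.get("trained_epochs", 0)) == 0:
        warnings.warn("embedding with an untrained model")
    return nn.encode(
        np.asarray(data.features, dtype=nn.DTYPE),
        graph.norm_operator.astype(nn.DTYPE),
        state,
        training=False,
    )


def cluster(embedding: np.ndarray, n_clusters: int, seed: int = 0) -> ClusterResult:
    """Top-30 PCs of the embedding, then k-means (k-means++, 10 restarts)."""
    embedding = np.asarray(embedding, dtype=float)
    n, d = embedding.shape
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds the number of spots {n}")
    n_comp = min(30, d, n - 1) if n > 1 else 1
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(
        embedding
    )
    km = KMeans(
        n_clusters=n_clusters, n_init=10, max_iter=300, random_state=seed
    ).fit(pcs)
    return ClusterResult(labels=km.labels_, n_clusters=n_clusters, embedding_pcs=pcs)


def reconstruct(
    data: SpotDataset, graph: SpatialGraph, state: nn.ModelState
) -> np.ndarray:
    """Unmasked encode -> decode pass (the denoised expression read-out)."""
    X = np.asarray(data.features, dtype=nn.DTYPE)
    if X.shape[1] != state.dims["n_features"]:
        raise ValueError(
            f"model was trained on {state.dims['n_features']} features, "
            f"dataset has {X.shape[1]}"
        )
    A_hat = graph.norm_operator.astype(nn.DTYPE)
    H = nn.encode(X, A_hat, state, training=False)
    return nn.decode(H, A_hat, state, training=False)


def denoise(
    data: SpotDataset,
    graph: SpatialGraph,
    cfg: Optional[TrainConfig] = None,
    state: Optional[nn.ModelState] = None,
) -> Tuple[np.ndarray, nn.ModelState, np.ndarray]:
    """Denoising variant: train on the scaled HVG matrix (no PCA), then
    return the reconstructed expression.  Returns (Z, state, loss_trace)."""
    cfg = cfg or TrainConfig()
    trace = np.empty((0, 3))
    if state is None:
        state, trace = train(data, graph, cfg)
    return reconstruct(data, graph, state), state, trace
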
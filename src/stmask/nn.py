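"""Numpy neural-network core: shared GCN encoder, remasking decoder, edge
discriminator, the two self-supervised losses, and an Adam optimizer.

Architecture
------------
encoder   H = A_hat @ PReLU(BN(A_hat @ X @ Wg0)) @ Wg1          (512 -> 256)
decoder   Z = A_hat @ PReLU(BN(H_tilde @ Wd0)) @ Wd1            (linear + GCN)
discrim.  D(h_i, h_j) = sigmoid(w2 . ReLU(W1 (h_i * h_j) + b1) + b2)

with ``A_hat = D^{-1/2} A D^{-1/2}`` and no self-loops or biases in the
graph layers, so an all-zero input (or an edgeless graph) propagates to an
all-zero embedding.  The reconstruction objective is the scaled cosine
error over masked nodes; the contrastive objective is a noise-contrastive
(binary cross-entropy) loss over masked-edge positives and sampled
non-neighbour negatives.  Forward passes cache intermediates; gradients are
hand-written and accumulate into a flat dict keyed like the parameters, so
the encoder can be shared by both channels simply by summing their
contributions.

All arithmetic is float32; batch normalisation uses batch statistics in
training mode and exponential running averages (momentum 0.1, eps 1e-5) at
inference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

DTYPE = np.float32
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
LOG_CLAMP = 1e-12
NORM_EPS = 1e-8


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """All learnable parameters plus BN running statistics.

    The encoder parameters (``Wg0``, ``Wg1``, ``bn_g_*``, ``prelu_g``) are a
    single set of arrays referenced by both the feature-masking and the
    edge-masking channel — sharing is by object identity, not by copy.
    """

    params: Dict[str, np.ndarray]
    buffers: Dict[str, np.ndarray]
    dims: Dict[str, int]

    ENCODER_KEYS = ("Wg0", "Wg1", "bn_g_gamma", "bn_g_beta", "prelu_g")
    DECODER_KEYS = ("Wd0", "Wd1", "bn_d_gamma", "bn_d_beta", "prelu_d")
    DISC_KEYS = ("W1", "b1", "w2", "b2")
    TOKEN_KEYS = ("x_token", "h_token")

    def zero_grads(self) -> Dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def save(self, path) -> None:
        """Single .npz archive with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{f"p_{k}": v for k, v in self.params.items()},
                 **{f"b_{k}": v for k, v in self.buffers.items()})
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(self.dims))

    @classmethod
    def load(cls, path) -> "ModelState":
        path = Path(path)
        dims = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            params = {k[2:]: z[k] for k in z.files if k.startswith("p_")}
            buffers = {k[2:]: z[k] for k in z.files if k.startswith("b_")}
        return cls(params=params, buffers=buffers, dims=dims)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


def init_model(
    n_features: int,
    seed: int = 0,
    enc_hidden: int = 512,
    latent: int = 256,
    dec_hidden: int = 256,
    disc_hidden: int = 256,
) -> ModelState:
    """Xavier-uniform weights, unit BN gains, zero tokens, PReLU slope 0.25."""
    rng = np.random.default_rng(seed)
    params = {
        "Wg0": _xavier(rng, n_features, enc_hidden),
        "Wg1": _xavier(rng, enc_hidden, latent),
        "bn_g_gamma": np.ones(enc_hidden, dtype=DTYPE),
        "bn_g_beta": np.zeros(enc_hidden, dtype=DTYPE),
        "prelu_g": np.array(0.25, dtype=DTYPE),
        "Wd0": _xavier(rng, latent, dec_hidden),
        "Wd1": _xavier(rng, dec_hidden, n_features),
        "bn_d_gamma": np.ones(dec_hidden, dtype=DTYPE),
        "bn_d_beta": np.zeros(dec_hidden, dtype=DTYPE),
        "prelu_d": np.array(0.25, dtype=DTYPE),
        "W1": _xavier(rng, latent, disc_hidden),
        "b1": np.zeros(disc_hidden, dtype=DTYPE),
        "w2": _xavier(rng, disc_hidden, 1)[:, 0],
        "b2": np.zeros((), dtype=DTYPE),
        "x_token": np.zeros(n_features, dtype=DTYPE),
        "h_token": np.zeros(latent, dtype=DTYPE),
    }
    buffers = {
        "bn_g_mean": np.zeros(enc_hidden, dtype=DTYPE),
        "bn_g_var": np.ones(enc_hidden, dtype=DTYPE),
        "bn_d_mean": np.zeros(dec_hidden, dtype=DTYPE),
        "bn_d_var": np.ones(dec_hidden, dtype=DTYPE),
    }
    dims = {
        "n_features": n_features,
        "enc_hidden": enc_hidden,
        "latent": latent,
        "dec_hidden": dec_hidden,
        "disc_hidden": disc_hidden,
    }
    return ModelState(params=params, buffers=buffers, dims=dims)


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def _bn_forward(x, gamma, beta, state: ModelState, prefix: str, training: bool):
    if training:
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        state.buffers[f"{prefix}_mean"] = (
            (1 - BN_MOMENTUM) * state.buffers[f"{prefix}_mean"] + BN_MOMENTUM * mean
        ).astype(DTYPE)
        state.buffers[f"{prefix}_var"] = (
            (1 - BN_MOMENTUM) * state.buffers[f"{prefix}_var"] + BN_MOMENTUM * var
        ).astype(DTYPE)
    else:
        mean = state.buffers[f"{prefix}_mean"]
        var = state.buffers[f"{prefix}_var"]
    ivar = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mean) * ivar
    y = gamma * xhat + beta
    return y, (xhat, ivar, gamma)


def _bn_backward(dy, cache):
    xhat, ivar, gamma = cache
    n = dy.shape[0]
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dx = (gamma * ivar / n) * (n * dy - dbeta - xhat * dgamma)
    return dx, dgamma, dbeta


def _prelu_forward(x, a):
    y = np.where(x > 0, x, a * x)
    return y, x


def _prelu_backward(dy, x, a):
    dx = dy * np.where(x > 0, DTYPE(1.0), a)
    da = np.sum(dy * np.where(x > 0, 0.0, x))
    return dx, np.asarray(da, dtype=DTYPE)


# ---------------------------------------------------------------------------
# encoder / decoder
# ---------------------------------------------------------------------------

def encode(
    features: np.ndarray,
    norm_adj: sp.spmatrix,
    state: ModelState,
    training: bool = False,
    return_cache: bool = False,
):
    """Two-layer GCN: ``A_hat PReLU(BN(A_hat X Wg0)) Wg1``."""
    p = state.params
    X = np.ascontiguousarray(features, dtype=DTYPE)
    if X.shape[1] != p["Wg0"].shape[0]:
        raise ValueError(
            f"encoder layer Wg0 expects {p['Wg0'].shape[0]} input features, "
            f"got {X.shape[1]}"
        )
    A = norm_adj
    XW = X @ p["Wg0"]
    U1 = (A @ XW).astype(DTYPE)
    B1, bn_cache = _bn_forward(U1, p["bn_g_gamma"], p["bn_g_beta"], state, "bn_g", training)
    P1, pr_cache = _prelu_forward(B1, p["prelu_g"])
    H = (A @ (P1 @ p["Wg1"])).astype(DTYPE)
    if return_cache:
        return H, {"X": X, "A": A, "P1": P1, "bn": bn_cache, "pr": pr_cache}
    return H


def encode_backward(dH, cache, state: ModelState, grads: Dict[str, np.ndarray]):
    """Accumulate encoder gradients; returns the gradient w.r.t. the input."""
    p = state.params
    A = cache["A"]
    dPW = (A @ dH.astype(DTYPE)).astype(DTYPE)  # A_hat is symmetric
    grads["Wg1"] += cache["P1"].T @ dPW
    dP1 = dPW @ p["Wg1"].T
    dB1, da = _prelu_backward(dP1, cache["pr"], p["prelu_g"])
    grads["prelu_g"] += da
    dU1, dgamma, dbeta = _bn_backward(dB1, cache["bn"])
    grads["bn_g_gamma"] += dgamma
    grads["bn_g_beta"] += dbeta
    dXW = (A @ dU1).astype(DTYPE)
    grads["Wg0"] += cache["X"].T @ dXW
    return dXW @ p["Wg0"].T


def remask(H: np.ndarray, masked_nodes: np.ndarray, token: np.ndarray) -> np.ndarray:
    """Replace the latent rows of masked nodes by the remask token."""
    Ht = H.copy()
    if len(masked_nodes):
        Ht[np.asarray(masked_nodes)] = np.asarray(token, dtype=H.dtype)
    return Ht


def decode(
    latent: np.ndarray,
    norm_adj: sp.spmatrix,
    state: ModelState,
    training: bool = False,
    return_cache: bool = False,
):
    """Linear layer then GCN layer: ``A_hat PReLU(BN(H Wd0)) Wd1``."""
    p = state.params
    Ht = np.ascontiguousarray(latent, dtype=DTYPE)
    if Ht.shape[1] != p["Wd0"].shape[0]:
        raise ValueError(
            f"decoder layer Wd0 expects {p['Wd0'].shape[0]} latent dims, got {Ht.shape[1]}"
        )
    U = Ht @ p["Wd0"]
    B, bn_cache = _bn_forward(U, p["bn_d_gamma"], p["bn_d_beta"], state, "bn_d", training)
    P, pr_cache = _prelu_forward(B, p["prelu_d"])
    Z = (norm_adj @ (P @ p["Wd1"])).astype(DTYPE)
    if return_cache:
        return Z, {"Ht": Ht, "A": norm_adj, "P": P, "bn": bn_cache, "pr": pr_cache}
    return Z


def decode_backward(dZ, cache, state: ModelState, grads: Dict[str, np.ndarray]):
    p = state.params
    dPW = (cache["A"] @ dZ.astype(DTYPE)).astype(DTYPE)
    grads["Wd1"] += cache["P"].T @ dPW
    dP = dPW @ p["Wd1"].T
    dB, da = _prelu_backward(dP, cache["pr"], p["prelu_d"])
    grads["prelu_d"] += da
    dU, dgamma, dbeta = _bn_backward(dB, cache["bn"])
    grads["bn_d_gamma"] += dgamma
    grads["bn_d_beta"] += dbeta
    grads["Wd0"] += cache["Ht"].T @ dU
    return dU @ p["Wd0"].T


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _row_cosine(X: np.ndarray, Z: np.ndarray):
    nx = np.linalg.norm(X, axis=1)
    nz = np.linalg.norm(Z, axis=1)
    denom = np.maximum(nx, NORM_EPS) * np.maximum(nz, NORM_EPS)
    c = (X * Z).sum(axis=1) / denom
    return np.clip(c, -1.0, 1.0), nx, nz, denom


def sce_loss(
    X: np.ndarray, Z: np.ndarray, masked_nodes: np.ndarray, gamma: float = 2.0
) -> float:
    """Scaled cosine error: mean over masked rows of ``(1 - cos(X_i, Z_i))^gamma``."""
    if len(masked_nodes) == 0:
        raise ValueError("sce_loss requires a non-empty masked-node set")
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    idx = np.asarray(masked_nodes)
    c, *_ = _row_cosine(np.asarray(X, float)[idx], np.asarray(Z, float)[idx])
    return float(np.mean((1.0 - c) ** gamma))


def sce_loss_grad(
    X: np.ndarray, Z: np.ndarray, masked_nodes: np.ndarray, gamma: float = 2.0
) -> Tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. Z (zero outside the masked rows)."""
    idx = np.asarray(masked_nodes)
    Xi = np.asarray(X, dtype=np.float64)[idx]
    Zi = np.asarray(Z, dtype=np.float64)[idx]
    c, nx, nz, denom = _row_cosine(Xi, Zi)
    loss = float(np.mean((1.0 - c) ** gamma))
    coef = -(gamma / len(idx)) * (1.0 - c) ** (gamma - 1.0)
    nz_safe = np.maximum(nz, NORM_EPS)
    dc_dZ = Xi / denom[:, None] - (c / nz_safe**2)[:, None] * Zi
    dZ = np.zeros_like(np.asarray(Z, dtype=np.float64))
    dZ[idx] = coef[:, None] * dc_dZ
    return loss, dZ.astype(DTYPE)


@dataclass
class EdgeSets:
    """Positive (masked) and sampled negative edge pairs for the NCE loss."""

    pos: np.ndarray  # (m, 2)
    neg: np.ndarray  # (m', 2)
    per_node_counts: np.ndarray  # positives incident to each node


def sample_negative_edges(
    pos_edges: np.ndarray,
    n_spots: int,
    neighbor_sets: Sequence[set],
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-node negative sampling matched to positive incidence counts.

    For every node ``i`` incident to ``n_i`` positive edges, draw ``n_i``
    partners uniformly without replacement from the non-neighbours
    ``V \\ ({i} | N(i))``.  Nodes adjacent to everything are skipped with a
    warning; a pool smaller than ``n_i`` yields the whole pool.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pos_edges = np.asarray(pos_edges).reshape(-1, 2)
    counts = np.bincount(pos_edges.ravel(), minlength=n_spots) if len(pos_edges) else np.zeros(n_spots, int)
    out: List[Tuple[int, int]] = []
    allowed = np.ones(n_spots, dtype=bool)
    for i in np.flatnonzero(counts):
        nbrs = list(neighbor_sets[i])
        allowed[nbrs] = False
        allowed[i] = False
        pool = np.flatnonzero(allowed)
        allowed[nbrs] = True
        allowed[i] = True
        if pool.size == 0:
            warnings.warn(f"node {i} is adjacent to every other node; skipped")
            continue
        ni = int(counts[i])
        if pool.size < ni:
            warnings.warn(f"node {i}: negative pool smaller than {ni}; taking all")
            chosen = pool
        else:
            chosen = rng.choice(pool, size=ni, replace=False)
        out.extend((i, int(v)) for v in np.atleast_1d(chosen))
    return np.array(out, dtype=int).reshape(-1, 2)


def sample_random_negative_edges(
    n_pairs: int,
    n_spots: int,
    adjacency: sp.spmatrix,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform non-edge pairs, ignoring per-node counts (ablation variant)."""
    A = adjacency.tocsr()
    out: List[Tuple[int, int]] = []
    while len(out) < n_pairs:
        i = rng.integers(0, n_spots, size=2 * (n_pairs - len(out)) + 8)
        j = rng.integers(0, n_spots, size=i.size)
        for a, b in zip(i, j):
            if a != b and A[a, b] == 0:
                out.append((int(a), int(b)))
                if len(out) == n_pairs:
                    break
    return np.array(out, dtype=int).reshape(-1, 2)


def build_edge_sets(
    pos_edges: np.ndarray,
    n_spots: int,
    neighbor_sets: Sequence[set],
    rng: np.random.Generator,
) -> EdgeSets:
    pos_edges = np.asarray(pos_edges).reshape(-1, 2)
    neg = sample_negative_edges(pos_edges, n_spots, neighbor_sets, rng=rng)
    counts = np.bincount(pos_edges.ravel(), minlength=n_spots) if len(pos_edges) else np.zeros(n_spots, int)
    return EdgeSets(pos=pos_edges, neg=neg, per_node_counts=counts)


def _disc_forward(H: np.ndarray, pairs: np.ndarray, state: ModelState):
    p = state.params
    u, v = pairs[:, 0], pairs[:, 1]
    M = H[u] * H[v]
    A1 = M @ p["W1"] + p["b1"]
    R = np.maximum(A1, 0.0)
    s = R @ p["w2"] + p["b2"]
    prob = 1.0 / (1.0 + np.exp(-s))
    return prob, {"M": M, "A1": A1, "R": R, "u": u, "v": v}


def _disc_backward(ds, cache, H, state: ModelState, grads, dH):
    p = state.params
    grads["w2"] += cache["R"].T @ ds
    grads["b2"] += ds.sum()
    dR = ds[:, None] * p["w2"][None, :]
    dA1 = dR * (cache["A1"] > 0)
    grads["W1"] += cache["M"].T @ dA1
    grads["b1"] += dA1.sum(axis=0)
    dM = dA1 @ p["W1"].T
    u, v = cache["u"], cache["v"]
    np.add.at(dH, u, (dM * H[v]).astype(DTYPE))
    np.add.at(dH, v, (dM * H[u]).astype(DTYPE))


def discriminate(hi: np.ndarray, hj: np.ndarray, state: ModelState) -> float:
    """Edge-existence probability for one node pair (symmetric in i, j)."""
    p = state.params
    m = np.asarray(hi, dtype=DTYPE) * np.asarray(hj, dtype=DTYPE)
    s = np.maximum(m @ p["W1"] + p["b1"], 0.0) @ p["w2"] + p["b2"]
    return float(1.0 / (1.0 + np.exp(-s)))


def nce_loss(H: np.ndarray, edge_sets: EdgeSets, state: ModelState) -> float:
    """Binary NCE over positive (masked) and negative (sampled) edges."""
    if len(edge_sets.pos) == 0:
        raise ValueError(
            "empty positive edge set: the contrastive channel requires edge "
            "masking (edge_mask_rate > 0)"
        )
    if len(edge_sets.neg) == 0:
        raise ValueError("empty negative edge set")
    H = np.asarray(H, dtype=DTYPE)
    p_pos, _ = _disc_forward(H, edge_sets.pos, state)
    p_neg, _ = _disc_forward(H, edge_sets.neg, state)
    return float(
        -(np.mean(np.log(np.maximum(p_pos, LOG_CLAMP)))
          + np.mean(np.log(np.maximum(1.0 - p_neg, LOG_CLAMP))))
    )


def nce_loss_grad(
    H: np.ndarray, edge_sets: EdgeSets, state: ModelState, grads: Dict[str, np.ndarray]
) -> Tuple[float, np.ndarray]:
    """Loss, gradient w.r.t. H; discriminator grads accumulate into ``grads``."""
    if len(edge_sets.pos) == 0 or len(edge_sets.neg) == 0:
        raise ValueError("nce_loss_grad requires non-empty positive and negative sets")
    H = np.asarray(H, dtype=DTYPE)
    dH = np.zeros_like(H)
    p_pos, cache_p = _disc_forward(H, edge_sets.pos, state)
    p_neg, cache_n = _disc_forward(H, edge_sets.neg, state)
    loss = float(
        -(np.mean(np.log(np.maximum(p_pos, LOG_CLAMP)))
          + np.mean(np.log(np.maximum(1.0 - p_neg, LOG_CLAMP))))
    )
    ds_pos = (-(1.0 - p_pos) / len(p_pos)).astype(DTYPE)
    ds_neg = (p_neg / len(p_neg)).astype(DTYPE)
    _disc_backward(ds_pos, cache_p, H, state, grads, dH)
    _disc_backward(ds_neg, cache_n, H, state, grads, dH)
    return loss, dH


def total_loss(l_sce: float, l_nce: float, lam: float) -> float:
    """Weighted objective ``(1 - lambda) * L_SCE + lambda * L_NCE``."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * l_sce + lam * l_nce


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 weight decay added to the gradient (classic coupling)."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g + self.wd * params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)
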
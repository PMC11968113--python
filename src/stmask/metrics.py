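"""Evaluation metrics for spatial-domain assignments and embeddings.

Covers clustering agreement (adjusted Rand index, best-matched accuracy),
spatial coherence of a labelling (discreteness index), spatial
autocorrelation of a per-spot signal (Moran's I, Geary's C), and the
batch-mixing / domain-purity trade-off of an integrated embedding (F1 of
normalised local inverse Simpson indices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix
from sklearn.neighbors import NearestNeighbors

from .graph import SpatialGraph


@dataclass
class MetricsReport:
    """One run's scores; fields are None when their inputs were absent."""

    ari: Optional[float] = None
    acc: Optional[float] = None
    dis: Optional[float] = None
    morans_i: Optional[Dict[str, float]] = None
    gearys_c: Optional[Dict[str, float]] = None
    f1lisi: Optional[float] = None

    def to_dict(self) -> Dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_labels(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors must have the same length")
    if pred.size < 2:
        raise ValueError("need at least 2 spots")
    return pred, truth


def ari(pred, truth) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    pred, truth = _check_labels(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def acc(pred, truth) -> float:
    """Best-matched accuracy: the largest fraction of agreeing spots over
    all injective cluster-to-class assignments (Hungarian matching on the
    contingency table)."""
    pred, truth = _check_labels(pred, truth)
    C = contingency_matrix(truth, pred)
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum() / pred.size)


def dis(labels, graph: SpatialGraph) -> float:
    """Discreteness index: mean fraction of a spot's spatial neighbours
    carrying a different label (0 = perfectly coherent domains).
    Isolated spots contribute 0."""
    labels = np.asarray(labels)
    A = graph.adjacency.tocsr()
    if A.shape[0] != labels.size:
        raise ValueError("labels must cover every graph node")
    deg = np.asarray(A.sum(axis=1)).ravel()
    # count neighbours with a different label for each spot
    codes = np.unique(labels, return_inverse=True)[1]
    frac = np.zeros(labels.size)
    indptr, indices = A.indptr, A.indices
    for i in range(labels.size):
        nbrs = indices[indptr[i]: indptr[i + 1]]
        if nbrs.size:
            frac[i] = np.mean(codes[nbrs] != codes[i])
    return float(frac.mean())


def _autocorr_inputs(values, graph: SpatialGraph):
    x = np.asarray(values, dtype=float)
    A = graph.adjacency.tocsr()
    if A.shape[0] != x.size:
        raise ValueError("values must cover every graph node")
    s0 = A.sum()
    if s0 == 0:
        raise ValueError("graph has no edges; spatial autocorrelation undefined")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("values are constant; spatial autocorrelation undefined")
    return x, z, A, s0, denom


def morans_i(values, graph: SpatialGraph) -> float:
    """Moran's I with binary spatial weights:
    ``I = (N / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2``."""
    x, z, A, s0, denom = _autocorr_inputs(values, graph)
    num = z @ (A @ z)
    return float(x.size / s0 * num / denom)


def gearys_c(values, graph: SpatialGraph) -> float:
    """Geary's C with binary spatial weights:
    ``C = ((N-1) / (2 S0)) * sum_ij w_ij (x_i - x_j)^2 / sum_i z_i^2``."""
    x, z, A, s0, denom = _autocorr_inputs(values, graph)
    # sum_ij w_ij (x_i - x_j)^2 = 2 [ sum_i d_i x_i^2 - x' A x ] for symmetric A
    deg = np.asarray(A.sum(axis=1)).ravel()
    quad = (deg * x**2).sum() - x @ (A @ x)
    return float((x.size - 1) / (2 * s0) * 2 * quad / denom)


# ---------------------------------------------------------------------------
# LISI
# ---------------------------------------------------------------------------

def _perplexity_weights(dists: np.ndarray, perplexity: float, tol: float = 1e-5,
                        max_iter: int = 64) -> np.ndarray:
    """Gaussian kernel weights over one spot's neighbours with the bandwidth
    tuned so the weight entropy matches log(perplexity) (t-SNE calibration)."""
    target = np.log(perplexity)
    beta, beta_min, beta_max = 1.0, -np.inf, np.inf
    d = dists - dists.min()
    for _ in range(max_iter):
        w = np.exp(-d * beta)
        sw = w.sum()
        if sw == 0:
            h = 0.0
            p = np.zeros_like(w)
        else:
            p = w / sw
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
        if abs(h - target) < tol:
            break
        if h > target:
            beta_min = beta
            beta = beta * 2 if np.isinf(beta_max) else (beta + beta_max) / 2
        else:
            beta_max = beta
            beta = beta / 2 if np.isinf(beta_min) else (beta + beta_min) / 2
    return p


def per_spot_lisi(embedding: np.ndarray, labels, perplexity: int = 30) -> np.ndarray:
    """Local inverse Simpson's index of label diversity around each spot.

    1 means a neighbourhood pure in one label; the number of distinct labels
    means perfect local mixing.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    codes = np.unique(labels, return_inverse=True)[1]
    n_label = codes.max() + 1
    n = embedding.shape[0]
    k = min(3 * perplexity, n - 1)
    nbr = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nbr.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    out = np.empty(n)
    for i in range(n):
        p = _perplexity_weights(dist[i], perplexity)
        probs = np.bincount(codes[idx[i]], weights=p, minlength=n_label)
        simpson = (probs**2).sum()
        out[i] = 1.0 / simpson if simpson > 0 else 1.0
    return out


def f1_lisi(embedding, batch, domain, perplexity: int = 30) -> float:
    """Harmonic mean of batch mixing and domain purity in one score.

    iLISI (over batch labels) is median-normalised to [0, 1] by
    ``(median - 1) / (B - 1)``; cLISI (over domain labels) likewise with the
    domain count, and enters as ``1 - cLISI_n`` (purity).  Their harmonic
    mean is clipped to [0, 1]: 1 means batches perfectly interleaved while
    domains stay separated.
    """
    batch, domain = np.asarray(batch), np.asarray(domain)
    n_batch = len(np.unique(batch))
    n_domain = len(np.unique(domain))
    if n_batch < 2:
        raise ValueError("f1_lisi requires at least 2 batches")
    if n_domain < 2:
        raise ValueError("f1_lisi requires at least 2 domains")
    ilisi = np.median(per_spot_lisi(embedding, batch, perplexity))
    clisi = np.median(per_spot_lisi(embedding, domain, perplexity))
    ilisi_n = (ilisi - 1.0) / (n_batch - 1.0)
    clisi_n = (clisi - 1.0) / (n_domain - 1.0)
    purity = 1.0 - clisi_n
    if purity + ilisi_n <= 0:
        return 0.0
    f1 = 2.0 * purity * ilisi_n / (purity + ilisi_n)
    return float(np.clip(f1, 0.0, 1.0))


def evaluate(
    pred=None,
    truth=None,
    graph: Optional[SpatialGraph] = None,
    embedding=None,
    batch=None,
    gene_values: Optional[Dict[str, np.ndarray]] = None,
    perplexity: int = 30,
) -> MetricsReport:
    """Compute every metric whose inputs were provided."""
    rep = MetricsReport()
    if pred is not None and truth is not None:
        rep.ari = ari(pred, truth)
        rep.acc = acc(pred, truth)
    if pred is not None and graph is not None:
        rep.dis = dis(pred, graph)
    if gene_values and graph is not None:
        rep.morans_i = {g: morans_i(v, graph) for g, v in gene_values.items()}
        rep.gearys_c = {g: gearys_c(v, graph) for g, v in gene_values.items()}
    if embedding is not None and batch is not None and pred is not None:
        rep.f1lisi = f1_lisi(embedding, batch, pred, perplexity)
    return rep
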
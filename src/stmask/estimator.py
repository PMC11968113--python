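"""scikit-learn style estimators wrapping the training pipeline.

:class:`DualMaskEmbedding` is the embedding learner (fit / transform /
fit_predict); :class:`ExpressionDenoiser` is the reconstruction variant that
returns denoised expression.  Both are transductive — the graph and the
spots seen at ``fit`` are the spots that get embedded — which matches how
spatial-domain models are used in practice.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import train as _train
from .data import SpotDataset
from .graph import SpatialGraph, build_knn_graph


def _resolve_inputs(X, coords, graph, n_neighbors):
    """Accept a SpotDataset or a plain feature matrix + coords/graph."""
    if isinstance(X, SpotDataset):
        data = X
        if data.features is None:
            raise ValueError(
                "SpotDataset has no processed features; run stmask.preprocess first"
            )
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix or a SpotDataset")
        if coords is None and graph is None:
            raise ValueError("provide spot coordinates (coords=) or a SpatialGraph")
        n = Xa.shape[0]
        data = SpotDataset(
            counts=np.zeros((n, 1)),
            coords=np.asarray(coords) if coords is not None else np.zeros((n, 2)),
            spot_ids=np.array([f"spot{i}" for i in range(n)], dtype=object),
            gene_ids=np.array(["g0"], dtype=object),
            features=Xa,
        )
    if graph is None:
        graph = build_knn_graph(data.coords[:, :2] if data.coords.shape[1] == 2
                                else data.coords, k=n_neighbors)
    return data, graph


class DualMaskEmbedding(TransformerMixin, BaseEstimator):
    """Self-supervised spot embedding via dual-masked graph learning.

    Parameters mirror the training configuration: ``node_mask_rate`` and
    ``edge_mask_rate`` are the masking fractions of the two channels,
    ``lam`` weights the contrastive loss against the reconstruction loss,
    and ``variant`` selects one of the ablation wirings.

    Attributes (after ``fit``)
    --------------------------
    model_state_ : the trained parameters
    graph_ : the spatial graph used
    embedding_ : the unmasked inference embedding of the training spots
    loss_trace_ : per-epoch (total, L_SCE, L_NCE)
    """

    def __init__(
        self,
        n_neighbors: int = 6,
        node_mask_rate: float = 0.3,
        edge_mask_rate: float = 0.4,
        lam: float = 0.7,
        epochs: int = 1000,
        lr: float = 1e-3,
        weight_decay: float = 2e-4,
        gamma: float = 2.0,
        variant: str = "full",
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.node_mask_rate = node_mask_rate
        self.edge_mask_rate = edge_mask_rate
        self.lam = lam
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.gamma = gamma
        self.variant = variant
        self.random_state = random_state

    def _config(self) -> _train.TrainConfig:
        return _train.TrainConfig(
            lr=self.lr,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            lam=self.lam,
            node_mask_rate=self.node_mask_rate,
            edge_mask_rate=self.edge_mask_rate,
            gamma=self.gamma,
            seed=self.random_state,
            variant=self.variant,
        )

    def fit(self, X, y=None, *, coords=None, graph: Optional[SpatialGraph] = None):
        data, graph = _resolve_inputs(X, coords, graph, self.n_neighbors)
        self.model_state_, self.loss_trace_ = _train.train(data, graph, self._config())
        self.graph_ = graph
        self._data = data
        self.embedding_ = _train.embed(data, graph, self.model_state_)
        return self

    def transform(self, X=None):
        """Embedding of the fitted spots (X, when given, must be feature-
        compatible with the training matrix and is encoded on the fitted
        graph)."""
        check_is_fitted(self, "model_state_")
        if X is None or X is self._data:
            return self.embedding_
        data, _ = _resolve_inputs(X, None, self.graph_, self.n_neighbors)
        return _train.embed(data, self.graph_, self.model_state_)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(None)

    def predict_domains(self, n_clusters: int) -> np.ndarray:
        """Cluster the fitted embedding into spatial domains."""
        check_is_fitted(self, "embedding_")
        res = _train.cluster(self.embedding_, n_clusters, seed=self.random_state)
        self.cluster_result_ = res
        return res.labels

    def fit_predict(self, X, y=None, *, n_clusters: int, coords=None, graph=None):
        self.fit(X, y, coords=coords, graph=graph)
        return self.predict_domains(n_clusters)


class ExpressionDenoiser(TransformerMixin, BaseEstimator):
    """Denoising variant: train on the scaled HVG matrix (no PCA) and read
    out the decoder's reconstruction as denoised expression."""

    def __init__(
        self,
        n_neighbors: int = 6,
        node_mask_rate: float = 0.3,
        edge_mask_rate: float = 0.4,
        lam: float = 0.7,
        epochs: int = 1000,
        lr: float = 1e-3,
        weight_decay: float = 2e-4,
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.node_mask_rate = node_mask_rate
        self.edge_mask_rate = edge_mask_rate
        self.lam = lam
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.random_state = random_state

    def fit(self, X, y=None, *, coords=None, graph: Optional[SpatialGraph] = None):
        data, graph = _resolve_inputs(X, coords, graph, self.n_neighbors)
        cfg = _train.TrainConfig(
            lr=self.lr,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            lam=self.lam,
            node_mask_rate=self.node_mask_rate,
            edge_mask_rate=self.edge_mask_rate,
            seed=self.random_state,
        )
        self.model_state_, self.loss_trace_ = _train.train(data, graph, cfg)
        self.graph_ = graph
        self._data = data
        return self

    def transform(self, X=None) -> np.ndarray:
        check_is_fitted(self, "model_state_")
        data = self._data if X is None else _resolve_inputs(X, None, self.graph_, self.n_neighbors)[0]
        return _train.reconstruct(data, self.graph_, self.model_state_)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(None)
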
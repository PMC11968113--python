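"""Count preprocessing: filter -> depth-normalise -> HVG -> scale -> PCA.

The pipeline order is fixed.  Gene filtering (detected in >= ``min_spots_per_gene``
spots) runs before the per-spot total-count filter, which in turn guarantees
the depth normalisation is well defined.  Highly variable genes are ranked
by a dispersion statistic (variance / mean) of the log1p-transformed
normalised matrix; scaling is per-gene z-scoring with the population
standard deviation; PCA is exact SVD with a deterministic sign convention.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import PreprocessConfig, SpotDataset

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """A filter removed every gene or every spot."""


def filter_counts(data: SpotDataset, cfg: PreprocessConfig) -> SpotDataset:
    """Drop weakly detected genes, then shallow spots.

    A gene survives when it has a non-zero count in at least
    ``cfg.min_spots_per_gene`` spots; afterwards a spot survives when its
    total count is at least ``cfg.min_counts_per_spot``.
    """
    counts = np.asarray(data.counts)
    gene_ok = (counts > 0).sum(axis=0) >= cfg.min_spots_per_gene
    if not gene_ok.any():
        raise EmptyResultError(
            f"no gene is detected in >= {cfg.min_spots_per_gene} spots"
        )
    data = data.subset_genes(np.flatnonzero(gene_ok))
    spot_ok = data.counts.sum(axis=1) >= cfg.min_counts_per_spot
    if not spot_ok.any():
        raise EmptyResultError(
            f"no spot reaches the total-count threshold {cfg.min_counts_per_spot}"
        )
    return data.subset_spots(np.flatnonzero(spot_ok))


def normalize_cpm(data: SpotDataset, scale_target: float = 1e6) -> SpotDataset:
    """Scale each spot's counts so its total equals ``scale_target``."""
    counts = np.asarray(data.counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ZeroDivisionError(
            "spot with zero total count reached normalisation; run filter_counts first"
        )
    return data.with_(features=counts / totals[:, None] * scale_target)


def select_hvg(data: SpotDataset, n_hvg: int = 2000) -> SpotDataset:
    """Keep the ``n_hvg`` most dispersed genes of the normalised matrix.

    Dispersion is variance / mean of ``log1p`` of the normalised values; a
    constant gene has zero variance and therefore ranks last.  When the
    panel already has at most ``n_hvg`` genes everything is kept.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    if data.features is None:
        raise ValueError("select_hvg expects the normalised matrix in .features")
    X = np.log1p(data.features)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    if data.n_genes <= n_hvg:
        return data
    # stable selection: rank by (-dispersion, gene index)
    order = np.lexsort((np.arange(len(disp)), -disp))
    keep = np.sort(order[:n_hvg])
    out = data.subset_genes(keep)
    return out.with_(features=data.features[:, keep])


def scale_features(data: SpotDataset) -> SpotDataset:
    """Z-score each gene (population SD); constant genes map to zeros."""
    X = np.asarray(data.features, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return data.with_(features=Z)


def _signed_svd(Xc: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with each right-singular vector's largest-|.| entry positive."""
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return U * signs[None, :], S, Vt * signs[:, None]


def reduce_pca(data: SpotDataset, n_pca: int = 200) -> SpotDataset:
    """Project the scaled matrix onto its top principal components.

    When the panel has fewer genes than requested components the scaled
    matrix is passed through unchanged (small imaging panels skip the
    reduction entirely); otherwise the output has
    ``min(n_pca, n_genes, n_spots - 1)`` columns.
    """
    X = np.asarray(data.features, dtype=float)
    n_spots, n_genes = X.shape
    if n_genes < n_pca:
        return data
    n_comp = min(n_pca, n_genes, n_spots - 1)
    Xc = X - X.mean(axis=0)
    _, S, Vt = _signed_svd(Xc)
    scores = Xc @ Vt[:n_comp].T
    return data.with_(features=scores)


def preprocess(data: SpotDataset, cfg: Optional[PreprocessConfig] = None) -> SpotDataset:
    """Run the full pipeline: filter -> CPM -> HVG -> scale -> (PCA)."""
    cfg = cfg or PreprocessConfig()
    out = filter_counts(data, cfg)
    out = normalize_cpm(out, cfg.scale_target)
    out = select_hvg(out, cfg.n_hvg)
    out = scale_features(out)
    if cfg.use_pca:
        out = reduce_pca(out, cfg.n_pca)
    bad = ~np.isfinite(out.features)
    if bad.any():  # pragma: no cover - defensive
        raise FloatingPointError("non-finite values in processed features")
    return out


class CountPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper over the count pipeline.

    ``fit_transform`` on a :class:`SpotDataset` (or a raw count array with
    ``coords`` omitted) returns the processed dataset / feature matrix.
    The transform is transductive — filters, HVG ranking, scaling moments
    and the PCA basis are all fitted on the data being transformed — so
    ``transform`` simply re-runs the pipeline.
    """

    def __init__(
        self,
        min_spots_per_gene: int = 50,
        min_counts_per_spot: int = 10,
        n_hvg: int = 2000,
        n_pca: int = 200,
        scale_target: float = 1e6,
        use_pca: bool = True,
    ):
        self.min_spots_per_gene = min_spots_per_gene
        self.min_counts_per_spot = min_counts_per_spot
        self.n_hvg = n_hvg
        self.n_pca = n_pca
        self.scale_target = scale_target
        self.use_pca = use_pca

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            min_spots_per_gene=self.min_spots_per_gene,
            min_counts_per_spot=self.min_counts_per_spot,
            n_hvg=self.n_hvg,
            n_pca=self.n_pca,
            scale_target=self.scale_target,
            use_pca=self.use_pca,
        )

    def fit(self, X, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X):
        self.fit(X)
        if isinstance(X, SpotDataset):
            return preprocess(X, self.config_)
        X = np.asarray(X)
        n = X.shape[0]
        ds = SpotDataset(
            counts=X,
            coords=np.zeros((n, 2)),
            spot_ids=np.array([f"spot{i}" for i in range(n)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(X.shape[1])], dtype=object),
        )
        return preprocess(ds, self.config_).features
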
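"""Core in-memory containers for spot-level spatial expression data.

The central object is :class:`SpotDataset`, a light transcript-by-spot
container carrying raw counts, the processed feature matrix the model
consumes, 2-D spatial coordinates and optional batch / ground-truth labels.
It converts losslessly to and from :class:`anndata.AnnData` so results can
flow into the scanpy ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


@dataclass
class SpotDataset:
    """Expression + coordinates for one (or several merged) tissue slices.

    Parameters
    ----------
    counts
        Raw non-negative count matrix, spots x genes.
    coords
        Spot centroids, spots x 2 (platform units), or spots x 3 after
        multi-slice stacking.
    spot_ids, gene_ids
        Unique string identifiers for rows and columns of ``counts``.
    features
        The processed model-input matrix (normalised / scaled / PCA),
        spots x n_features.  ``None`` until preprocessing has run.
    batch
        Optional per-spot slice-of-origin label for merged datasets.
    truth
        Optional per-spot ground-truth domain label for evaluation.
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    features: Optional[np.ndarray] = None
    batch: Optional[np.ndarray] = None
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        n = self.counts.shape[0]
        if self.coords.shape[0] != n:
            raise ValueError(
                f"coords has {self.coords.shape[0]} rows but counts has {n} spots"
            )
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be N x 2 (or N x 3 for stacked slices)")
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length mismatch")
        if len(np.unique(self.spot_ids.astype(str))) != n:
            raise ValueError("spot_ids must be unique")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids length mismatch")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")
        for name in ("batch", "truth"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if len(lab) != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, lab)

    # -- basic geometry -------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_features(self) -> int:
        if self.features is None:
            raise AttributeError("dataset has no processed features yet")
        return self.features.shape[1]

    # -- functional updates ---------------------------------------------
    def with_(self, **kw) -> "SpotDataset":
        """Return a shallow copy with the given fields replaced."""
        return replace(self, **kw)

    def subset_spots(self, idx: np.ndarray) -> "SpotDataset":
        idx = np.asarray(idx)
        return SpotDataset(
            counts=self.counts[idx],
            coords=self.coords[idx],
            spot_ids=self.spot_ids[idx],
            gene_ids=self.gene_ids,
            features=None if self.features is None else self.features[idx],
            batch=None if self.batch is None else self.batch[idx],
            truth=None if self.truth is None else self.truth[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "SpotDataset":
        idx = np.asarray(idx)
        return SpotDataset(
            counts=self.counts[:, idx],
            coords=self.coords,
            spot_ids=self.spot_ids,
            gene_ids=self.gene_ids[idx],
            features=None,  # feature matrix is gene-derived; invalidate
            batch=self.batch,
            truth=self.truth,
        )

    # -- interop ---------------------------------------------------------
    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (counts in ``.layers['counts']``)."""
        import anndata as ad
        import pandas as pd

        X = self.features if self.features is not None else self.counts.astype(float)
        obs = pd.DataFrame(index=self.spot_ids.astype(str))
        if self.batch is not None:
            obs["batch"] = pd.Categorical(self.batch.astype(str))
        if self.truth is not None:
            obs["truth"] = pd.Categorical(self.truth.astype(str))
        adata = ad.AnnData(X=np.asarray(X, dtype=float), obs=obs)
        if self.features is not None and self.counts.shape[1] == X.shape[1]:
            adata.layers["counts"] = np.asarray(self.counts, dtype=float)
        adata.obsm["spatial"] = self.coords.copy()
        if self.features is None:
            adata.var_names = self.gene_ids.astype(str)
        return adata

    @classmethod
    def from_anndata(cls, adata, counts_layer: Optional[str] = None) -> "SpotDataset":
        counts = adata.layers[counts_layer] if counts_layer else adata.X
        if hasattr(counts, "toarray"):
            counts = counts.toarray()
        coords = adata.obsm["spatial"]
        return cls(
            counts=np.asarray(counts),
            coords=np.asarray(coords),
            spot_ids=np.asarray(adata.obs_names, dtype=object),
            gene_ids=np.asarray(adata.var_names, dtype=object),
            batch=np.asarray(adata.obs["batch"]) if "batch" in adata.obs else None,
            truth=np.asarray(adata.obs["truth"]) if "truth" in adata.obs else None,
        )


@dataclass
class PreprocessConfig:
    """Knobs for the count-processing pipeline.

    ``min_spots_per_gene`` keeps genes detected (non-zero) in at least that
    many spots; ``min_counts_per_spot`` keeps spots whose total count reaches
    the threshold.  ``scale_target`` is the per-spot total after depth
    normalisation (counts-per-million by default).  ``use_pca=False`` feeds
    the scaled highly-variable-gene matrix straight to the model, the setup
    used for expression denoising and for low-plex imaging panels.
    """

    min_spots_per_gene: int = 50
    min_counts_per_spot: int = 10
    n_hvg: int = 2000
    n_pca: int = 200
    scale_target: float = 1e6
    use_pca: bool = True

    def __post_init__(self) -> None:
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.n_pca < 1:
            raise ValueError("n_pca must be >= 1")
        if self.min_spots_per_gene < 0 or self.min_counts_per_spot < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.scale_target <= 0:
            raise ValueError("scale_target must be positive")
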
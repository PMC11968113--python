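"""Seeded synthetic spatial-transcriptomics generator.

Produces grid-arranged spots partitioned into spatially contiguous domains
(horizontal bands or Voronoi blobs), domain-specific marker-gene programs,
negative-binomial counts with multiplicative dropout, and optional per-slice
batch shifts — the structural features of sequencing-based spatial data that
the embedding model is designed to exploit, at a scale small enough for
tests.  Everything is deterministic per seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .data import SpotDataset

__all__ = ["SimConfig", "simulate_slice", "simulate_multislice", "smoke_config"]


@dataclass
class SimConfig:
    """Configuration of one simulated slice.

    ``effect_size`` is the log-scale mean shift of a marker gene inside its
    own domain.  ``dispersion`` is the negative-binomial overdispersion
    ``alpha`` in ``var = mu + alpha * mu**2`` (0 gives Poisson counts).
    ``dropout`` zeroes each count independently, emulating the sparsity of
    spot-level data.  ``base_log_mean`` sets the typical background
    expression level; per-gene baselines scatter around it.
    """

    grid: Tuple[int, int] = (30, 30)
    k_domains: int = 4
    layout: str = "bands"  # "bands" | "blobs"
    n_genes: int = 200
    markers_per_domain: int = 10
    effect_size: float = 1.0
    dispersion: float = 0.3
    dropout: float = 0.6
    batch_shift_sd: float = 0.0
    base_log_mean: float = 0.7
    baseline_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if rows * cols < self.k_domains:
            raise ValueError("grid too small for the requested number of domains")
        if self.markers_per_domain * self.k_domains > self.n_genes:
            raise ValueError("markers_per_domain * k_domains exceeds n_genes")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.layout not in ("bands", "blobs"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def smoke_config(**overrides) -> SimConfig:
    """The default small fixture: 30x30 grid, 4 band domains, 200 genes,
    10 markers per domain, effect 1.0, dropout 0.6, seed 0."""
    return dataclasses.replace(SimConfig(), **overrides)


def _domain_labels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = cfg.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if cfg.layout == "bands":
        # horizontal bands of (nearly) equal height
        edges = np.linspace(0, rows, cfg.k_domains + 1)
        dom = np.searchsorted(edges, rr.ravel(), side="right") - 1
        return np.clip(dom, 0, cfg.k_domains - 1)
    # Voronoi blobs around random centres
    centers = np.column_stack(
        [rng.uniform(0, rows, cfg.k_domains), rng.uniform(0, cols, cfg.k_domains)]
    )
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _log_means(cfg: SimConfig, domains: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Spots x genes matrix of log-scale expected expression (the clean signal)."""
    n_spots = domains.size
    baseline = rng.normal(cfg.base_log_mean, cfg.baseline_sd, size=cfg.n_genes)
    logmu = np.tile(baseline, (n_spots, 1))
    for d in range(cfg.k_domains):
        lo = d * cfg.markers_per_domain
        hi = lo + cfg.markers_per_domain
        logmu[np.ix_(domains == d, np.arange(lo, hi))] += cfg.effect_size
    return logmu


def _sample_counts(
    logmu: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    mu = np.exp(logmu)
    if cfg.dispersion > 0:
        # NB as a gamma-Poisson mixture: shape 1/alpha, scale mu*alpha
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    if cfg.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= cfg.dropout)
    return counts.astype(np.int64)


def simulate_slice(
    cfg: SimConfig, *, slice_id: str = "s0", rng: Optional[np.random.Generator] = None
) -> Tuple[SpotDataset, np.ndarray]:
    """Simulate one slice.

    Returns the dataset (with planted ``truth`` labels) and the clean
    spots x genes log-mean matrix used to generate it, for denoising tests.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)  # x=col, y=row
    domains = _domain_labels(cfg, rng)
    logmu = _log_means(cfg, domains, rng)
    counts = _sample_counts(logmu, cfg, rng)
    n = rows * cols
    ds = SpotDataset(
        counts=counts,
        coords=coords,
        spot_ids=np.array([f"{slice_id}_spot{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"gene{j}" for j in range(cfg.n_genes)], dtype=object),
        truth=domains.astype(np.int64),
    )
    return ds, logmu


def simulate_multislice(
    cfg: SimConfig,
    n_slices: int = 2,
    misalign=None,
) -> List[SpotDataset]:
    """Simulate serial slices sharing one domain layout.

    Each slice receives an independent gene-wise log-shift drawn from
    ``Normal(0, batch_shift_sd)`` before count sampling (a batch effect),
    and slices after the first are optionally rigidly misaligned (for
    registration tests).  Batch labels are attached.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    domains = _domain_labels(cfg, rng)
    logmu = _log_means(cfg, domains, rng)

    slices = []
    for s in range(n_slices):
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes)
        counts = _sample_counts(logmu + shift[None, :], cfg, rng)
        xy = coords.copy()
        if s > 0 and misalign is not None:
            xy = misalign.apply(xy)
        n = rows * cols
        slices.append(
            SpotDataset(
                counts=counts,
                coords=xy,
                spot_ids=np.array(
                    [f"s{s}_spot{i}" for i in range(n)], dtype=object
                ),
                gene_ids=np.array(
                    [f"gene{j}" for j in range(cfg.n_genes)], dtype=object
                ),
                batch=np.full(n, f"s{s}", dtype=object),
                truth=domains.astype(np.int64),
            )
        )
    return slices
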
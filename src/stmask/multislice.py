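"""Multi-slice alignment and merging.

Serial (vertical) sections are registered by rigid point-to-point ICP and
stacked along a z-axis whose spacing defaults to the within-slice spot
pitch, so a single 3-D KNN graph can connect spots across slices.
Side-by-side (horizontal) sections are translated so the right edge of the
first slice meets the left edge of the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .data import SpotDataset
from .graph import median_nn_distance


@dataclass
class RigidTransform2D:
    """Rotation (det +1) plus translation; applied as ``x R^T + t``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(2), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self after other: x -> self(other(x))."""
        return RigidTransform2D(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform2D":
        Rt = self.rotation.T
        return RigidTransform2D(rotation=Rt, translation=-Rt @ self.translation)


def _procrustes(src: np.ndarray, dst: np.ndarray) -> RigidTransform2D:
    """Least-squares rigid fit mapping src onto dst (known correspondence)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-12 * max(S[0], 1.0):
        warnings.warn("degenerate point configuration; translation-only fit")
        return RigidTransform2D(translation=cd - cs)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    return RigidTransform2D(rotation=R, translation=cd - R @ cs)


def align_icp(
    ref_coords: np.ndarray,
    moving_coords: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> Tuple[RigidTransform2D, np.ndarray]:
    """Rigid point-to-point ICP registering ``moving`` onto ``ref``.

    Each iteration matches every moving point to its nearest reference
    point, fits the least-squares rotation + translation by SVD of the
    cross-covariance, and applies it; stops when the mean correspondence
    distance improves by less than ``tol``.  Because nearest-neighbour ICP
    only converges locally, the iteration is restarted from a small fixed
    set of initial orientations (identity and principal-axes alignments,
    each after centroid alignment) and the solution with the lowest final
    correspondence distance is kept.  Deterministic.  Returns the composed
    transform and the aligned coordinates.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(moving_coords, dtype=float)
    if ref.shape[0] < 3 or mov.shape[0] < 3:
        raise ValueError("ICP needs at least 3 points per slice")
    tree = cKDTree(ref)

    def _principal_axes(pts):
        c = pts - pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(c, full_matrices=False)
        V = Vt.T
        if np.linalg.det(V) < 0:
            V[:, 1] *= -1
        return V

    rot_pi = np.array([[-1.0, 0.0], [0.0, -1.0]])
    R_pca = _principal_axes(ref) @ _principal_axes(mov).T
    inits = [np.eye(2), R_pca, R_pca @ rot_pi, rot_pi]

    best = None
    for R0 in inits:
        start = RigidTransform2D(rotation=R0)
        # centroid pre-alignment after the trial rotation: pure translations
        # become exact in one step
        start = RigidTransform2D(
            translation=ref.mean(axis=0) - start.apply(mov).mean(axis=0)
        ).compose(start)
        cur = start.apply(mov)
        total = start
        prev_err = np.inf
        err = float(tree.query(cur)[0].mean())
        for _ in range(max_iter):
            if prev_err - err < tol:
                break
            prev_err = err
            dist, idx = tree.query(cur)
            step = _procrustes(cur, ref[idx])
            cur = step.apply(cur)
            total = step.compose(total)
            err = float(tree.query(cur)[0].mean())
        if best is None or err < best[0]:
            best = (err, total, cur)
    return best[1], best[2]


def stack_slices(
    aligned: Sequence[np.ndarray], z_gap: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack aligned 2-D slices along z (slice s at ``z = s * z_gap``).

    ``z_gap`` defaults to the median nearest-neighbour spacing of the first
    slice.  Returns the (N_total, 3) coordinates and a slice-index column.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 slices")
    coord_list = [np.asarray(c, dtype=float) for c in aligned]
    if z_gap is None:
        z_gap = median_nn_distance(coord_list[0])
    if z_gap <= 0:
        raise ValueError("z_gap must be positive")
    coords = np.vstack(
        [np.column_stack([c[:, :2], np.full(len(c), s * z_gap)])
         for s, c in enumerate(coord_list)]
    )
    slice_idx = np.concatenate(
        [np.full(len(c), s, dtype=int) for s, c in enumerate(coord_list)]
    )
    return coords, slice_idx


def align_horizontal(
    batch1_coords: np.ndarray,
    batch2_coords: np.ndarray,
    edge_quantile: float = 0.01,
) -> np.ndarray:
    """Translate batch2 so its left edge meets batch1's right edge.

    ``dx = max(x1) - min(x2)``; ``dy = ybar1 - ybar2`` where ``ybar1`` is the
    mean y of batch1's rightmost points (x within the top ``edge_quantile``
    of its x range) and ``ybar2`` the mean y of batch2's leftmost points.
    Batch1 stays fixed; the shifted batch2 coordinates are returned.
    """
    b1 = np.asarray(batch1_coords, dtype=float)
    b2 = np.asarray(batch2_coords, dtype=float)
    if b1.size == 0 or b2.size == 0:
        raise ValueError("both batches must be non-empty")
    dx = b1[:, 0].max() - b2[:, 0].min()
    right = b1[b1[:, 0] >= np.quantile(b1[:, 0], 1.0 - edge_quantile)]
    left = b2[b2[:, 0] <= np.quantile(b2[:, 0], edge_quantile)]
    dy = right[:, 1].mean() - left[:, 1].mean()
    return b2 + np.array([dx, dy])


def merge_slices(slices: Sequence[SpotDataset]) -> SpotDataset:
    """Concatenate aligned slices into one dataset with batch labels.

    Genes must agree across slices.  Coordinates are used as provided
    (align first; 3-D stacking is handled by the graph builder).
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices")
    genes = slices[0].gene_ids
    for s in slices[1:]:
        if not np.array_equal(s.gene_ids, genes):
            raise ValueError("slices must share an identical gene panel")
    batch = np.concatenate(
        [s.batch if s.batch is not None else np.full(s.n_spots, f"s{i}", dtype=object)
         for i, s in enumerate(slices)]
    )
    truths = [s.truth for s in slices]
    return SpotDataset(
        counts=np.vstack([s.counts for s in slices]),
        coords=np.vstack([s.coords[:, :2] for s in slices]),
        spot_ids=np.concatenate([s.spot_ids for s in slices]),
        gene_ids=genes,
        batch=batch,
        truth=None if any(t is None for t in truths) else np.concatenate(truths),
    )
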
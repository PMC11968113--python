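"""Readers and writers for the standard on-disk formats.

Counts come in as a 10x-style HDF5 feature-barcode matrix, a MatrixMarket
triplet directory (matrix.mtx + barcodes.tsv + features.tsv), or a dense
CSV/TSV (spots x genes).  Coordinates are a CSV with columns
``spot_id,x,y``; labels are CSVs with ``spot_id,label``.  Spots present in
only one of counts/coordinates are dropped with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import SpotDataset

logger = logging.getLogger(__name__)

__all__ = [
    "load_dataset",
    "read_labels",
    "save_processed",
    "load_processed",
    "write_labels",
]


class FormatError(ValueError):
    """Input file could not be parsed in the declared format."""


class AlignmentError(ValueError):
    """Counts and coordinates share no spot identifiers."""


def _read_10x_h5(path: Path):
    """Minimal 10x HDF5 feature-barcode reader (v3 'matrix' group layout)."""
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path}: no 'matrix' group; not a 10x HDF5 file")
        g = f["matrix"]
        data = g["data"][:]
        indices = g["indices"][:]
        indptr = g["indptr"][:]
        shape = tuple(g["shape"][:])  # (n_genes, n_barcodes), CSC over barcodes
        barcodes = g["barcodes"][:].astype(str)
        feat = g["features"]["name"][:].astype(str) if "features" in g else g["genes"][:].astype(str)
    M = sp.csc_matrix((data, indices, indptr), shape=shape)
    counts = np.asarray(M.T.todense())  # spots x genes
    return counts, barcodes, feat


def _read_mtx_dir(path: Path):
    mtx = next((path / n for n in ("matrix.mtx", "matrix.mtx.gz") if (path / n).exists()), None)
    if mtx is None:
        raise FormatError(f"{path}: no matrix.mtx found")
    M = scipy.io.mmread(mtx).tocsr()
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str).values
    features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].astype(str).values
    # MatrixMarket convention is genes x barcodes; transpose to spots x genes
    if M.shape == (len(features), len(barcodes)):
        counts = np.asarray(M.T.todense())
    elif M.shape == (len(barcodes), len(features)):
        counts = np.asarray(M.todense())
    else:
        raise FormatError(
            f"{path}: matrix shape {M.shape} matches neither orientation of "
            f"({len(features)} features, {len(barcodes)} barcodes)"
        )
    return counts, barcodes, features


def _read_dense_csv(path: Path):
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, index_col=0, sep=sep)
    return df.values, df.index.astype(str).values, df.columns.astype(str).values


def load_dataset(path, fmt: str, coords_path) -> SpotDataset:
    """Load counts in the given format and align them with a coordinate CSV.

    ``fmt`` is one of ``"10x-h5"``, ``"mtx-dir"``, ``"csv"``.  The
    coordinate table must have columns ``spot_id, x, y``.  Only the spot-id
    intersection is kept (warned when non-trivial); zero overlap raises
    :class:`AlignmentError`.
    """
    path, coords_path = Path(path), Path(coords_path)
    if not path.exists():
        raise FormatError(f"counts path does not exist: {path}")
    if not coords_path.exists():
        raise FormatError(f"coordinates path does not exist: {coords_path}")
    readers = {"10x-h5": _read_10x_h5, "mtx-dir": _read_mtx_dir, "csv": _read_dense_csv}
    if fmt not in readers:
        raise FormatError(f"unknown format {fmt!r}; expected one of {sorted(readers)}")
    try:
        counts, barcodes, genes = readers[fmt](path)
    except (OSError, ValueError, KeyError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc

    cdf = pd.read_csv(coords_path)
    cdf.columns = [c.strip().lower() for c in cdf.columns]
    if not {"spot_id", "x", "y"} <= set(cdf.columns):
        raise FormatError(f"{coords_path}: expected columns spot_id,x,y")
    cdf = cdf.set_index(cdf["spot_id"].astype(str))

    barcodes = np.asarray(barcodes, dtype=str)
    common = [b for b in barcodes if b in cdf.index]
    if not common:
        raise AlignmentError("no overlapping spot ids between counts and coordinates")
    n_dropped = (len(barcodes) - len(common)) + (len(cdf) - len(common))
    if n_dropped:
        logger.warning(
            "dropping %d spots present in only one of counts/coordinates", n_dropped
        )
    pos = {b: i for i, b in enumerate(barcodes)}
    rows = np.array([pos[b] for b in common])
    coords = cdf.loc[common, ["x", "y"]].values.astype(float)
    return SpotDataset(
        counts=np.asarray(counts)[rows],
        coords=coords,
        spot_ids=np.asarray(common, dtype=object),
        gene_ids=np.asarray(genes, dtype=object),
    )


def read_labels(path, data: Optional[SpotDataset] = None) -> np.ndarray:
    """Read a ``spot_id,label`` CSV; reordered to match ``data`` if given."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"spot_id", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns spot_id,label")
    ser = df.set_index(df["spot_id"].astype(str))["label"]
    if data is None:
        return ser.values
    return ser.reindex(data.spot_ids.astype(str)).values


def write_labels(path, data: SpotDataset, labels: np.ndarray) -> None:
    pd.DataFrame({"spot_id": data.spot_ids.astype(str), "label": labels}).to_csv(
        path, index=False
    )


def save_processed(path, data: SpotDataset) -> None:
    """Serialise a processed dataset to HDF5 (/features, /coords, /ids)."""
    with h5py.File(path, "w") as f:
        if data.features is not None:
            f.create_dataset("features", data=np.asarray(data.features, dtype=np.float64))
        f.create_dataset("counts", data=np.asarray(data.counts))
        f.create_dataset("coords", data=np.asarray(data.coords, dtype=np.float64))
        ids = f.create_group("ids")
        str_dt = h5py.string_dtype()

        def as_str(arr):
            return np.asarray(arr).astype(str).astype(object)

        ids.create_dataset("spots", data=as_str(data.spot_ids), dtype=str_dt)
        ids.create_dataset("genes", data=as_str(data.gene_ids), dtype=str_dt)
        if data.batch is not None:
            f.create_dataset("batch", data=as_str(data.batch), dtype=str_dt)
        if data.truth is not None:
            f.create_dataset("truth", data=as_str(data.truth), dtype=str_dt)


def load_processed(path) -> SpotDataset:
    with h5py.File(path, "r") as f:
        return SpotDataset(
            counts=f["counts"][:],
            coords=f["coords"][:],
            spot_ids=f["ids/spots"][:].astype(str).astype(object),
            gene_ids=f["ids/genes"][:].astype(str).astype(object),
            features=f["features"][:] if "features" in f else None,
            batch=f["batch"][:].astype(str).astype(object) if "batch" in f else None,
            truth=f["truth"][:].astype(str).astype(object) if "truth" in f else None,
        )
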
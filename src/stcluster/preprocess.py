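"""Loading and preprocessing of spatial expression data.

The pipeline mirrors the standard single-cell workflow: optionally select
highly variable genes (only when the panel is larger than the target), then
log(1 + x) transform and per-gene standardisation.  Tissue masking (removing
spots outside the tissue area) is assumed done upstream by the platform's
own tooling; the loader only warns about all-zero spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .dataset import SpatialDataset

__all__ = ["PreprocessConfig", "load_dataset", "select_hvg",
           "normalize_log_scale", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """n_hvg: number of variable genes kept; selection is applied only when
    the dataset has more than `hvg_threshold` genes (small targeted panels,
    e.g. 33-gene osmFISH, are used whole)."""

    n_hvg: int = 3000
    hvg_threshold: int = 3000
    log_transform: bool = True
    scale: bool = True

    def validate(self) -> None:
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")


# ---------------------------------------------------------------------------
# loading

def load_dataset(path, fmt: str | None = None, coords_path=None,
                 genes_path=None, barcodes_path=None) -> SpatialDataset:
    """Read a dataset from h5ad or MatrixMarket + TSV/CSV sidecar files.

    For fmt="mtx" the matrix is spots x genes (or genes x spots, transposed
    when the sidecar lengths identify it); coords_path is a CSV with columns
    spot_id, x, y and optionally label, matched to barcodes by spot_id.
    """
    path = Path(path)
    if fmt is None:
        fmt = "h5ad" if path.suffix == ".h5ad" else "mtx"
    if fmt == "h5ad":
        import anndata as ad

        dataset = SpatialDataset.from_anndata(ad.read_h5ad(path))
    elif fmt == "mtx":
        dataset = _load_mtx(path, coords_path, genes_path, barcodes_path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    totals = np.asarray(dataset.expression.sum(axis=1)).ravel()
    if np.any(totals == 0):
        warnings.warn(f"{int((totals == 0).sum())} all-zero spots present; "
                      "tissue filtering is assumed to have been done upstream")
    return dataset


def _load_mtx(mtx_path, coords_path, genes_path, barcodes_path) -> SpatialDataset:
    if coords_path is None:
        raise ValueError("no spatial information: coords CSV required for MTX input")
    mtx_path = Path(mtx_path)
    base = mtx_path.parent
    genes_path = Path(genes_path) if genes_path else base / "genes.tsv"
    barcodes_path = Path(barcodes_path) if barcodes_path else base / "barcodes.tsv"

    mat = scipy.io.mmread(mtx_path).tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape == (len(genes), len(barcodes)) and len(genes) != len(barcodes):
        mat = mat.T.tocsr()
    if mat.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(barcodes)} barcodes "
            f"x {len(genes)} genes")

    coords_df = pd.read_csv(coords_path)
    if len(coords_df) != len(barcodes):
        raise ValueError(
            f"coordinate rows ({len(coords_df)}) do not match spot count "
            f"({len(barcodes)})")
    coords_df = coords_df.set_index(coords_df["spot_id"].astype(str))
    missing = [b for b in barcodes if b not in coords_df.index]
    if missing:
        raise ValueError(f"coordinates missing for spots {missing[:5]}")
    coords_df = coords_df.loc[barcodes]
    labels = coords_df["label"].to_numpy() if "label" in coords_df else None
    return SpatialDataset(expression=mat,
                          coords=coords_df[["x", "y"]].to_numpy(float),
                          spot_ids=barcodes, gene_ids=genes, labels=labels)


# ---------------------------------------------------------------------------
# highly variable genes

def _normalized_dispersion(x: np.ndarray, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Seurat-style normalized dispersion.

    Per-gene dispersion is var/mean of log1p values; genes are split into
    equal-frequency mean bins and the dispersion is z-scored within each bin
    (degenerate bins — size one or zero spread — get z = 0).  Returns
    (z, raw dispersion); ranking uses z with raw dispersion as tiebreak.
    """
    logx = np.log1p(x)
    mean = logx.mean(axis=0)
    var = logx.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, len(order)))
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        mu = disp[b].mean()
        sd = disp[b].std(ddof=1) if len(b) > 1 else 0.0
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    return z, disp


def select_hvg(dataset: SpatialDataset, n_hvg: int = 3000,
               threshold: int | None = None) -> SpatialDataset:
    """Keep the n_hvg genes with highest normalized dispersion.

    When the dataset has no more than `threshold` genes (default: n_hvg) the
    dataset is returned unchanged — selection is meant for genome-wide panels
    only.  Selection is a pure subset: values untouched, genes ordered by
    their original position.
    """
    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    if threshold is None:
        threshold = n_hvg
    if dataset.n_genes <= threshold or dataset.n_genes <= n_hvg:
        return dataset
    z, disp = _normalized_dispersion(dataset.dense())
    # primary key: binned z-score; ties broken by raw dispersion, then index
    order = np.lexsort((np.arange(dataset.n_genes), -disp, -z))
    return dataset.subset_genes(np.sort(order[:n_hvg]))


# ---------------------------------------------------------------------------
# log transform + scaling

def normalize_log_scale(dataset: SpatialDataset, log_transform: bool = True,
                        scale: bool = True) -> SpatialDataset:
    """log(1 + x) then per-gene centring to mean 0, variance 1 (ddof = 1).

    Constant genes (zero variance) map to all-zero columns.  Applying the
    transform twice is a likely mistake and triggers a warning.
    """
    if dataset.scaled:
        warnings.warn("dataset appears to be scaled already; "
                      "re-applying normalize_log_scale is not idempotent")
    x = dataset.dense()
    if np.any(x < 0):
        raise ValueError("negative expression values: input must be raw counts "
                         "or non-negative normalized values")
    if log_transform:
        x = np.log1p(x)
    if scale:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
        x = x - mean
        nz = sd > 0
        x[:, nz] /= sd[nz]
        x[:, ~nz] = 0.0
    out = dataset.copy()
    out.expression = x
    out.scaled = True
    return out


def preprocess(dataset: SpatialDataset,
               config: PreprocessConfig = PreprocessConfig()) -> SpatialDataset:
    """HVG selection followed by log transform and scaling."""
    config.validate()
    out = select_hvg(dataset, config.n_hvg, config.hvg_threshold)
    if config.log_transform or config.scale:
        out = normalize_log_scale(out, config.log_transform, config.scale)
    return out
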
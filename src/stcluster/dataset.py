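"""The in-memory container shared by every stage: spots x genes + coordinates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["SpatialDataset"]

SPATIAL_KEY = "spatial"  # obsm slot for coordinates, by community convention
LABEL_KEY = "domain"


@dataclass
class SpatialDataset:
    """A spot-by-gene expression matrix with per-spot 2-D coordinates.

    expression may be dense or scipy-sparse; coords is (n_spots, 2); labels
    are optional integer domain annotations used only for evaluation.
    """

    expression: np.ndarray | sp.spmatrix
    coords: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None
    scaled: bool = False  # set once normalize_log_scale has been applied

    def __post_init__(self):
        n, g = self.expression.shape
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length does not match spot count")
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lists do not match matrix shape")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicated spot_ids")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def dense(self) -> np.ndarray:
        x = self.expression
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)

    def copy(self) -> "SpatialDataset":
        return SpatialDataset(
            expression=self.expression.copy(),
            coords=self.coords.copy(),
            spot_ids=list(self.spot_ids),
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels.copy(),
            scaled=self.scaled,
        )

    def subset_genes(self, idx: np.ndarray) -> "SpatialDataset":
        idx = np.asarray(idx)
        return SpatialDataset(
            expression=self.expression[:, idx].copy(),
            coords=self.coords.copy(),
            spot_ids=list(self.spot_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels.copy(),
            scaled=self.scaled,
        )

    # ---- AnnData interop -------------------------------------------------
    def to_anndata(self):
        import anndata as ad
        import pandas as pd

        adata = ad.AnnData(
            X=self.expression.copy(),
            obs=pd.DataFrame(index=self.spot_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obsm[SPATIAL_KEY] = self.coords.copy()
        if self.labels is not None:
            adata.obs[LABEL_KEY] = pd.Categorical(self.labels.astype(str))
        adata.uns["scaled"] = bool(self.scaled)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpatialDataset":
        if SPATIAL_KEY not in adata.obsm:
            raise ValueError(
                "no spatial information: AnnData lacks an obsm['spatial'] array")
        labels = None
        if LABEL_KEY in adata.obs:
            labels = np.asarray(
                adata.obs[LABEL_KEY].astype("category").cat.codes, dtype=int)
        x = adata.X
        if sp.issparse(x):
            x = x.copy()
        else:
            x = np.asarray(x).copy()
        return cls(
            expression=x,
            coords=np.asarray(adata.obsm[SPATIAL_KEY], dtype=float),
            spot_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            labels=labels,
            scaled=bool(adata.uns.get("scaled", False)),
        )

    def write_h5ad(self, path) -> None:
        self.to_anndata().write_h5ad(path)
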
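"""Core in-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A gene x cell non-negative expression matrix with per-cell cluster labels.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array of TPM-like, non-negative
        expression values.
    gene_ids
        Unique gene symbols, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    clusters
        Mapping from cell barcode to cluster label; every cell must be
        labelled.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    clusters: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x cell array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self.clusters = pd.Series(self.clusters)
        missing = [c for c in self.cell_ids if c not in self.clusters.index]
        if missing:
            raise ValueError(f"cells without cluster label: {missing[:5]} ...")
        self.clusters = self.clusters.loc[self.cell_ids]

    # -- basic queries ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def cluster_labels(self) -> list:
        """Distinct cluster labels in first-appearance order."""
        return list(dict.fromkeys(self.clusters))

    def cluster_columns(self, cluster) -> np.ndarray:
        """Column indices of the cells in ``cluster``."""
        mask = (self.clusters == cluster).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown cluster {cluster!r}")
        return np.flatnonzero(mask)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene {exc.args[0]!r}") from exc

    def submatrix(self, genes, cluster) -> np.ndarray:
        """Dense block of ``genes`` x cells-of-``cluster``."""
        rows = self.gene_index(genes)
        cols = self.cluster_columns(cluster)
        return self.values[np.ix_(rows, cols)]

    # -- interoperability ------------------------------------------------
    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.values.T.copy(),
            obs=pd.DataFrame({"cluster": self.clusters.values}, index=self.cell_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        return adata

    @classmethod
    def from_anndata(cls, adata, cluster_key: str = "cluster") -> "ExpressionMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(
            values=np.asarray(X).T,
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            clusters=pd.Series(adata.obs[cluster_key].values, index=adata.obs_names),
        )
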
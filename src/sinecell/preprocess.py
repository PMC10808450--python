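"""Per-cluster gene filtering ahead of co-oscillation inference.

Two sequential criteria select the genes worth testing:

* zero-filter — a gene must be non-zero in at least 80% of the
  cluster's cells (inclusive), because zeros degrade the paired-sine
  statistic;
* variance-filter — among the zero-filtered genes, keep those whose
  expression variance is strictly greater than the mean of those
  variances ("highly variable").

Both criteria are scale-invariant: multiplying the matrix by a positive
constant changes neither the zero pattern nor the variance-vs-mean
comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["FilterReport", "zero_filter", "variance_filter", "filter_cascade"]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-cluster cascade counts: expressed -> variable -> oscillators."""

    cluster: object
    n_expressed: int
    n_variable: int
    n_oscillators: int | None = None

    def to_row(self) -> dict:
        return {
            "cluster": self.cluster,
            "n_expressed": self.n_expressed,
            "n_variable": self.n_variable,
            "n_oscillators": self.n_oscillators,
        }


def zero_filter(
    matrix: ExpressionMatrix, cluster, threshold: float = 0.8
) -> list[str]:
    """Genes expressed (value > 0) in at least ``threshold`` of the cells.

    The comparison is inclusive: with 5 cells and threshold 0.8, a gene
    non-zero in exactly 4 cells is kept. Gene order follows the matrix.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cols = matrix.cluster_columns(cluster)
    frac_nonzero = (matrix.values[:, cols] > 0).mean(axis=1)
    keep = frac_nonzero >= threshold
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def variance_filter(
    matrix: ExpressionMatrix, cluster, candidate_genes: list[str]
) -> list[str]:
    """Candidates whose variance strictly exceeds the mean candidate variance.

    Variance is the sample variance (denominator n-1) across the
    cluster's cells, computed over ``candidate_genes`` only; the
    threshold is the mean of those variances. Ties at exactly the mean
    are excluded ("higher than").
    """
    if len(candidate_genes) == 0:
        logger.warning("variance_filter: empty candidate set for cluster %r", cluster)
        return []
    block = matrix.submatrix(candidate_genes, cluster)
    variances = block.var(axis=1, ddof=1)
    keep = variances > variances.mean()
    return [g for g, k in zip(candidate_genes, keep) if k]


def filter_cascade(
    matrix: ExpressionMatrix, cluster, threshold: float = 0.8
) -> tuple[list[str], list[str], FilterReport]:
    """Run both filters and report the cascade counts."""
    expressed = zero_filter(matrix, cluster, threshold=threshold)
    variable = variance_filter(matrix, cluster, expressed)
    report = FilterReport(
        cluster=cluster, n_expressed=len(expressed), n_variable=len(variable)
    )
    return expressed, variable, report


def filter_report_table(reports: list[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
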
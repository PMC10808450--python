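"""Paired-sine co-oscillation inference.

Within an unsynchronized but homogeneous cell population, a gene whose
expression oscillates traces a sinusoid of the cells' latent phase; two
genes oscillating at the same frequency with a relative phase shift psi
lie on an ellipse in their joint scatter. After rescaling each gene to
[-1, 1], a pair (x, y) that follows ``x_s = sin(theta_s)``,
``y_s = sin(theta_s + psi)`` satisfies the implicit ellipse identity::

    x^2 + y^2 - 2 x y cos(psi) - sin^2(psi) = 0     for every cell s

The co-oscillation statistic epsilon is the mean squared violation of
this identity, minimized over the phase shift:

    epsilon(x, y) = min_{psi in [0, pi]}
        (1/S) * sum_s (x_s^2 + y_s^2 - 2 x_s y_s cos(psi) - sin^2(psi))^2

epsilon is zero for a perfectly co-oscillating pair at the true phase
shift and grows with noise or frequency mismatch; it is symmetric in
(x, y) and needs no cell ordering. Minimizing over [0, pi] suffices
because the objective depends on psi only through cos(psi).

Significance uses a pooled permutation null (cell labels shuffled
independently per gene, destroying any cross-cell alignment), add-one
empirical p-values and Benjamini-Hochberg FDR. Significant pairs form
an undirected network; modularity communities of size >= 2 define the
inferred oscillators.

Implementation note: with c = cos(psi), the objective is a quartic
polynomial in c whose five coefficients are cell-wise moments of the
pair, so the psi-minimization is evaluated exactly on a dense grid and
refined by ternary search without touching the per-cell data again.
This makes the all-pairs scan a handful of G x G matrix products.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities

from .config import PipelineConfig
from .containers import ExpressionMatrix
from .preprocess import FilterReport, filter_cascade

__all__ = [
    "RescaledMatrix",
    "Community",
    "OscillatorCall",
    "rescale_to_unit",
    "rescale_matrix",
    "pair_sine_distance",
    "all_pair_statistics",
    "permutation_null",
    "pair_pvalue",
    "bh_adjust",
    "build_network",
    "extract_communities",
    "infer_oscillators",
]

logger = logging.getLogger(__name__)

PAIR_TABLE_COLUMNS = ["gene_i", "gene_j", "epsilon", "psi_hat", "p_value", "q_value"]


@dataclass
class RescaledMatrix:
    """Gene x cell matrix with every row linearly mapped onto [-1, 1]."""

    values: np.ndarray
    gene_ids: list[str]
    cluster: object = None


@dataclass
class Community:
    """A non-singleton set of genes from the significant-pair network."""

    genes: frozenset
    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class OscillatorCall:
    """End-to-end result of co-oscillation inference for one cluster."""

    cluster: object
    oscillators: set
    communities: list[Community]
    pair_table: pd.DataFrame
    report: FilterReport
    network: nx.Graph = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def rescale_to_unit(values: np.ndarray) -> np.ndarray:
    """Linear map ``x -> 2 (x - min) / (max - min) - 1`` onto [-1, 1]."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant vector")
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def rescale_matrix(block: np.ndarray, gene_ids: list[str], cluster=None) -> RescaledMatrix:
    """Row-wise :func:`rescale_to_unit` of a gene x cell block."""
    scaled = np.empty_like(np.asarray(block, dtype=float))
    for i in range(block.shape[0]):
        scaled[i] = rescale_to_unit(block[i])
    return RescaledMatrix(values=scaled, gene_ids=list(gene_ids), cluster=cluster)


# ---------------------------------------------------------------------------
# the paired-sine objective as a quartic in cos(psi)
# ---------------------------------------------------------------------------
# With b_s = x_s y_s and d_s = x_s^2 + y_s^2 - 1 the per-cell residual is
# d_s - 2 b_s c + c^2 (c = cos psi), so the summed squared residual is
#   q(c) = S c^4 - 4 (sum b) c^3 + (2 sum d + 4 sum b^2) c^2
#          - 4 (sum d b) c + sum d^2
# and epsilon = min_c q(c) / S over c = cos(psi), psi in [0, pi].


def _pair_coeffs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Quartic coefficients [c^4 .. c^0] for each row-pair of x, y."""
    b = x * y
    d = x * x + y * y - 1.0
    S = x.shape[-1]
    coeffs = np.stack(
        [
            np.full(b.shape[:-1], float(S)),
            -4.0 * b.sum(axis=-1),
            2.0 * d.sum(axis=-1) + 4.0 * (b * b).sum(axis=-1),
            -4.0 * (d * b).sum(axis=-1),
            (d * d).sum(axis=-1),
        ],
        axis=-1,
    )
    return np.atleast_2d(coeffs)


def _allpair_coeffs(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quartic coefficients for all unordered row pairs of R, via moments."""
    G, S = R.shape
    R2 = R * R
    R3 = R2 * R
    P1 = R @ R.T          # sum x y
    P2 = R2 @ R2.T        # sum x^2 y^2
    P3 = R3 @ R.T         # sum x^3 y
    m2 = R2.sum(axis=1)
    m4 = (R2 * R2).sum(axis=1)
    iu, ju = np.triu_indices(G, k=1)
    B = P1[iu, ju]
    B2 = P2[iu, ju]
    D = m2[iu] + m2[ju] - S
    E = P3[iu, ju] + P3[ju, iu] - B
    F = m4[iu] + m4[ju] + S + 2.0 * B2 - 2.0 * m2[iu] - 2.0 * m2[ju]
    coeffs = np.stack(
        [np.full(B.shape, float(S)), -4.0 * B, 2.0 * D + 4.0 * B2, -4.0 * E, F],
        axis=-1,
    )
    return iu, ju, coeffs


def _eval_q(coeffs: np.ndarray, c: np.ndarray) -> np.ndarray:
    a4, a3, a2, a1, a0 = coeffs.T
    return (((a4 * c + a3) * c + a2) * c + a1) * c + a0


def _minimize_quartic(
    coeffs: np.ndarray, n_grid: int = 1000, n_refine: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize q(cos psi) over psi in [0, pi] per coefficient row.

    Dense psi grid to locate the global basin, then ternary search in
    the bracketing interval (the objective is smooth; the grid is far
    finer than the spacing of its at-most-three critical points).
    Returns (min value, argmin psi).
    """
    psi_grid = np.linspace(0.0, np.pi, n_grid)
    powers = np.vander(np.cos(psi_grid), 5, increasing=False).T  # (5, n_grid)
    n = coeffs.shape[0]
    best_idx = np.empty(n, dtype=int)
    chunk = max(1, int(4e6 // n_grid))
    for start in range(0, n, chunk):
        Q = coeffs[start : start + chunk] @ powers
        best_idx[start : start + chunk] = np.argmin(Q, axis=1)
    delta = np.pi / (n_grid - 1)
    lo = np.clip(psi_grid[best_idx] - delta, 0.0, np.pi)
    hi = np.clip(psi_grid[best_idx] + delta, 0.0, np.pi)
    for _ in range(n_refine):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        f1 = _eval_q(coeffs, np.cos(m1))
        f2 = _eval_q(coeffs, np.cos(m2))
        left = f1 < f2
        hi = np.where(left, m2, hi)
        lo = np.where(left, lo, m1)
    psi_hat = 0.5 * (lo + hi)
    # rounding can leave a perfect fit at -1e-16; epsilon is non-negative
    q_min = np.maximum(_eval_q(coeffs, np.cos(psi_hat)), 0.0)
    return q_min, psi_hat


def pair_sine_distance(
    x: np.ndarray, y: np.ndarray, n_grid: int = 1000
) -> tuple[float, float]:
    """Minimized paired-sine distance and optimal phase shift for one pair.

    Both vectors must be rescaled to [-1, 1] and of equal length >= 3.
    Returns ``(epsilon, psi_hat)`` with epsilon reported per cell
    (summed squared residual divided by the number of cells).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need 1-D vectors of length >= 3")
    coeffs = _pair_coeffs(x, y)
    q_min, psi_hat = _minimize_quartic(coeffs, n_grid=n_grid)
    return float(q_min[0] / x.size), float(psi_hat[0])


def all_pair_statistics(
    rescaled: RescaledMatrix, n_grid: int = 1000
) -> pd.DataFrame:
    """epsilon and psi_hat for every unordered gene pair.

    Genes are paired in the row order of ``rescaled`` (callers sort
    rows lexicographically for deterministic output); ``gene_i`` always
    precedes ``gene_j`` in that order.
    """
    R = rescaled.values
    if R.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    iu, ju, coeffs = _allpair_coeffs(R)
    q_min, psi_hat = _minimize_quartic(coeffs, n_grid=n_grid)
    genes = np.asarray(rescaled.gene_ids)
    return pd.DataFrame(
        {
            "gene_i": genes[iu],
            "gene_j": genes[ju],
            "epsilon": q_min / R.shape[1],
            "psi_hat": psi_hat,
        }
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def permutation_null(
    rescaled: RescaledMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    n_grid: int = 1000,
) -> np.ndarray:
    """Pooled null sample of epsilon under cell-label permutation.

    Each draw picks two distinct genes at random, permutes each gene's
    values independently across cells (destroying co-oscillation while
    keeping the marginals), and records the paired-sine distance. The
    null is shared across all pairs of the cluster, which is valid under
    exchangeability and keeps the cost linear in ``n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    R = rescaled.values
    G, S = R.shape
    if G < 2:
        raise ValueError("need at least 2 genes for a permutation null")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gi = np.empty(n_perm, dtype=int)
    gj = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        gi[b], gj[b] = rng.choice(G, size=2, replace=False)
    X = rng.permuted(R[gi], axis=1)
    Y = rng.permuted(R[gj], axis=1)
    coeffs = _pair_coeffs(X, Y)
    q_min, _ = _minimize_quartic(coeffs, n_grid=n_grid)
    return q_min / S


def pair_pvalue(epsilon_obs, null_sample: np.ndarray):
    """Add-one left-tail permutation p-value (small epsilon = better fit).

    ``p = (1 + #{null <= epsilon_obs}) / (B + 1)``. Vectorized over
    ``epsilon_obs``.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    sorted_null = np.sort(null_sample)
    obs = np.asarray(epsilon_obs, dtype=float)
    count = np.searchsorted(sorted_null, obs, side="right")
    p = (1.0 + count) / (null_sample.size + 1.0)
    return float(p) if obs.ndim == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    ``q_i = min_{j: rank(j) >= rank(i)} m * p_(j) / rank(j)``; monotone
    in the p-value ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# network and communities
# ---------------------------------------------------------------------------

def build_network(pair_table: pd.DataFrame, alpha: float = 0.05) -> nx.Graph:
    """Undirected network with an edge for every pair with q <= alpha.

    Every tested gene appears as a node, so genes without a significant
    partner remain visible as isolates.
    """
    if "q_value" not in pair_table.columns:
        raise ValueError("pair table has no q_value column; run bh_adjust first")
    G = nx.Graph()
    G.add_nodes_from(pd.unique(pair_table[["gene_i", "gene_j"]].values.ravel()))
    sig = pair_table[pair_table["q_value"] <= alpha]
    for row in sig.itertuples(index=False):
        G.add_edge(row.gene_i, row.gene_j, epsilon=row.epsilon, psi_hat=row.psi_hat)
    return G


def extract_communities(network: nx.Graph) -> list[Community]:
    """Modularity communities of the significant-pair network.

    Greedy modularity maximization runs per connected component
    (components of one or two nodes are returned as-is); communities of
    size 1 are dropped. Sorted by size descending, ties by the
    lexicographically first gene.
    """
    communities: list[frozenset] = []
    for component in nx.connected_components(network):
        if len(component) == 1:
            communities.append(frozenset(component))
        elif len(component) == 2:
            communities.append(frozenset(component))
        else:
            sub = network.subgraph(component)
            communities.extend(frozenset(c) for c in greedy_modularity_communities(sub))
    kept = [Community(genes=c) for c in communities if len(c) >= 2]
    kept.sort(key=lambda c: (-c.size, min(c.genes)))
    return kept


# ---------------------------------------------------------------------------
# end-to-end per-cluster call
# ---------------------------------------------------------------------------

def infer_oscillators(
    matrix: ExpressionMatrix,
    cluster,
    config: PipelineConfig | None = None,
) -> OscillatorCall:
    """Filter -> rescale -> all-pairs statistic -> FDR -> communities.

    The inferred oscillators are the union of the non-singleton
    communities of the significant-pair network. Deterministic given
    ``config.seed``.
    """
    config = config or PipelineConfig()
    cols = matrix.cluster_columns(cluster)
    if cols.size < config.min_cells:
        raise ValueError(
            f"cluster {cluster!r} has {cols.size} cells, fewer than "
            f"min_cells={config.min_cells}"
        )
    expressed, variable, report = filter_cascade(
        matrix, cluster, threshold=config.zero_threshold
    )
    empty_table = pd.DataFrame(columns=PAIR_TABLE_COLUMNS)
    if len(variable) < 2:
        warnings.warn(
            f"cluster {cluster!r}: fewer than 2 genes survive filtering; "
            "empty oscillator call"
        )
        report.n_oscillators = 0
        return OscillatorCall(cluster, set(), [], empty_table, report, nx.Graph())

    genes = sorted(variable)
    block = matrix.submatrix(genes, cluster)
    if config.log_transform:
        block = np.log1p(block)
    rescaled = rescale_matrix(block, genes, cluster=cluster)

    pair_table = all_pair_statistics(rescaled, n_grid=config.psi_grid_points)
    rng = np.random.default_rng(config.seed)
    null = permutation_null(
        rescaled, n_perm=config.n_perm, seed=rng, n_grid=config.psi_grid_points
    )
    pair_table["p_value"] = pair_pvalue(pair_table["epsilon"].to_numpy(), null)
    pair_table["q_value"] = bh_adjust(pair_table["p_value"].to_numpy())

    network = build_network(pair_table, alpha=config.alpha)
    communities = extract_communities(network)
    oscillators = set().union(*(c.genes for c in communities)) if communities else set()
    report.n_oscillators = len(oscillators)
    logger.info(
        "cluster %r: %d expressed, %d variable, %d oscillators in %d communities",
        cluster, report.n_expressed, report.n_variable,
        len(oscillators), len(communities),
    )
    return OscillatorCall(cluster, oscillators, communities, pair_table, report, network)
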
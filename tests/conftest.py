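import numpy as np
import pandas as pd
import pytest

from sinecell import ExpressionMatrix


@pytest.fixture
def toy_matrix():
    """5-cell single-cluster matrix with hand-designed zero/variance structure.

    Gene layout (values across the 5 cells of cluster "c"):
      g_all4   nonzero in 4/5 cells -> passes the 80% zero-filter (inclusive)
      g_all5   nonzero everywhere, high variance
      g_only3  nonzero in 3/5 cells -> fails zero-filter
      g_zero   all zeros -> fails zero-filter
      g_flat   constant positive -> passes zero-filter, variance 0
    """
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 0.0],   # g_all4
            [1.0, 10.0, 1.0, 10.0, 1.0], # g_all5
            [5.0, 5.0, 5.0, 0.0, 0.0],   # g_only3
            [0.0, 0.0, 0.0, 0.0, 0.0],   # g_zero
            [2.0, 2.0, 2.0, 2.0, 2.0],   # g_flat
        ]
    )
    gene_ids = ["g_all4", "g_all5", "g_only3", "g_zero", "g_flat"]
    cell_ids = [f"cell{i}" for i in range(5)]
    return ExpressionMatrix(
        values, gene_ids, cell_ids, pd.Series("c", index=cell_ids)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_pair_distance(x, y, n_grid=1_000_000, chunk=100_000):
    """Independent oracle: dense psi-grid minimization of the summed
    squared ellipse residual, computed directly from the per-cell
    definition (no shared code with the package's optimizer)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = x * x + y * y
    B = x * y
    psi_full = np.linspace(0.0, np.pi, n_grid)
    best = np.inf
    best_psi = 0.0
    for lo in range(0, n_grid, chunk):
        psi = psi_full[lo : lo + chunk]
        c = np.cos(psi)
        s2 = np.sin(psi) ** 2
        r = A[:, None] - 2.0 * B[:, None] * c[None, :] - s2[None, :]
        tot = np.einsum("ij,ij->j", r, r)
        i = int(np.argmin(tot))
        if tot[i] < best:
            best, best_psi = float(tot[i]), float(psi[i])
    return best / x.size, best_psi
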
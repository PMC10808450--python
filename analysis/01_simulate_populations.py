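#!/usr/bin/env python
"""Simulate the study inputs: three 'tumours' of unsynchronized cells,
each with two subclusters carrying a planted 20-gene co-oscillating
group over a noise background, plus live-imaging reporter trace cohorts
(17 h rhythm vs flat control). Everything downstream reads from here.
"""
import pandas as pd

from sinecell import SyntheticMatrixSpec, SyntheticTraceSpec, generate_cosc_matrix, generate_trace
from sinecell.containers import ExpressionMatrix
from sinecell.io import write_expression_matrix, write_traces
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20240901

TUMOURS = ("T1", "T2", "T3")
SUBCLUSTERS = ("s0", "s1")


def simulate_tumour(name: str, seed: int) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two subclusters of 300 cells sharing the same gene universe."""
    blocks, cells, clusters, truths = [], [], [], []
    for k, sub in enumerate(SUBCLUSTERS):
        spec = SyntheticMatrixSpec(seed=seed + k, cluster_label=f"{name}_{sub}")
        m, truth = generate_cosc_matrix(spec)
        blocks.append(m.values)
        cells += [f"{name}_{sub}_{c}" for c in m.cell_ids]
        clusters += [f"{name}_{sub}"] * m.n_cells
        truths.append(truth.genes.assign(cluster=f"{name}_{sub}"))
        gene_ids = m.gene_ids
    matrix = ExpressionMatrix(
        np.hstack(blocks), gene_ids, cells, pd.Series(clusters, index=cells)
    )
    return matrix, pd.concat(truths)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(TUMOURS):
        matrix, truth = simulate_tumour(name, SEED + 10 * i)
        write_expression_matrix(matrix, OUT / name)
        truth.rename_axis("gene").to_csv(OUT / name / "ground_truth.tsv", sep="\t")
        print(f"{name}: {matrix.n_genes} genes x {matrix.n_cells} cells "
              f"({len(SUBCLUSTERS)} subclusters)")

    traces = []
    for i in range(20):
        traces.append(generate_trace(SyntheticTraceSpec(
            seed=SEED + i, trace_id=f"sig{i}", condition="proliferative")))
        traces.append(generate_trace(SyntheticTraceSpec(
            amplitude=0.0, seed=SEED + 100 + i, trace_id=f"ctrl{i}",
            condition="proliferative", channel="control")))
        traces.append(generate_trace(SyntheticTraceSpec(
            amplitude=120.0, offset=800.0, seed=SEED + 200 + i,
            trace_id=f"qsig{i}", condition="quiescent")))
    write_traces(traces, OUT / "traces.csv")
    print(f"traces: {len(traces)} written (periodic + flat control cohorts)")


if __name__ == "__main__":
    main()
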
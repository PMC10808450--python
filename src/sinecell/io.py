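"""Readers and writers for the pipeline's file dialects.

Expression matrices travel either as a Matrix Market (MTX) triplet
directory — ``matrix.mtx`` (1-based coordinate format) with companion
``genes.tsv`` and ``barcodes.tsv`` (barcode + cluster column) — or as a
dense CSV with genes as rows and a separate cluster TSV. Gene lists are
plain text (one symbol per line) or GMT. Traces are long-format CSV.

Every table this module writes starts with comment lines recording the
configuration hash and seed, so two runs with identical config + seed
produce byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sparse

from .config import PipelineConfig
from .containers import ExpressionMatrix
from .genelists import GeneSet
from .periodicity import Trace

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_traces",
    "write_traces",
    "write_table",
    "read_table",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    mtx = path / "matrix.mtx"
    genes_f = path / "genes.tsv"
    barcodes_f = path / "barcodes.tsv"
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise FileNotFoundError(f"missing {f}")
    values = sio.mmread(mtx)
    if sparse.issparse(values):
        values = values.toarray()
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
    bc = pd.read_csv(barcodes_f, sep="\t", header=None)
    if bc.shape[1] < 2:
        raise ValueError(f"{barcodes_f}: expected barcode<TAB>cluster columns")
    cells = bc[0].astype(str).tolist()
    clusters = pd.Series(bc[1].values, index=cells)
    if values.shape != (len(genes), len(cells)):
        raise ValueError(
            f"{mtx}: matrix is {values.shape}, companions describe "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return ExpressionMatrix(values, genes, cells, clusters)


def _read_csv_matrix(path: Path, clusters_path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene row {dup!r}")
    if clusters_path is None:
        raise ValueError("CSV dialect needs a clusters TSV (cell<TAB>cluster)")
    cl = pd.read_csv(clusters_path, sep="\t", header=None)
    clusters = pd.Series(cl[1].values, index=cl[0].astype(str))
    return ExpressionMatrix(
        df.to_numpy(float), list(df.index.astype(str)),
        list(df.columns.astype(str)), clusters,
    )


def read_expression_matrix(
    path, dialect: str = "mtx", clusters_path=None
) -> ExpressionMatrix:
    """Load a gene x cell matrix (``mtx`` directory or dense ``csv``)."""
    path = Path(path)
    if dialect == "mtx":
        return _read_mtx_dir(path)
    if dialect == "csv":
        return _read_csv_matrix(path, clusters_path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path, dialect: str = "mtx") -> Path:
    """Write a matrix as an MTX triplet directory or dense CSV pair."""
    path = Path(path)
    if dialect == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(matrix.values))
        (path / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
        pd.DataFrame(
            {"barcode": matrix.cell_ids, "cluster": matrix.clusters.values}
        ).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        return path
    if dialect == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids
        ).to_csv(path)
        pd.DataFrame(
            {"barcode": matrix.cell_ids, "cluster": matrix.clusters.values}
        ).to_csv(path.with_suffix(".clusters.tsv"), sep="\t", header=False, index=False)
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path, format: str = "txt", uppercase: bool = False):
    """Read gene sets: ``txt`` (one symbol/line) or ``gmt`` (one set/line).

    Returns a single :class:`GeneSet` for txt, a list of them for gmt.
    Symbols are whitespace-trimmed and deduplicated; blank lines are
    ignored; an empty file yields an empty set with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if format == "txt":
        symbols = [line.strip() for line in text.splitlines() if line.strip()]
        if not symbols:
            logger.warning("gene list %s is empty", path)
        return GeneSet(path.stem, symbols, uppercase=uppercase)
    if format == "gmt":
        sets = []
        for line in text.splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, members")
            name, _desc, *members = fields
            sets.append(GeneSet(name, [m for m in members if m.strip()], uppercase=uppercase))
        if not sets:
            logger.warning("GMT file %s is empty", path)
        return sets
    raise ValueError(f"unknown gene-list format {format!r}")


def write_gene_list(geneset: GeneSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(sorted(geneset.genes)) + ("\n" if geneset.genes else ""))
    return path


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def read_traces(path) -> list[Trace]:
    """Read a long-format trace CSV: time_h,intensity,trace_id[,condition,channel]."""
    df = pd.read_csv(path)
    required = {"time_h", "intensity", "trace_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns {sorted(required)}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("time_h")
        traces.append(
            Trace(
                time_h=grp["time_h"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                trace_id=str(tid),
                condition=str(grp["condition"].iloc[0]) if "condition" in grp else "",
                channel=str(grp["channel"].iloc[0]) if "channel" in grp else "",
            )
        )
    return traces


def write_traces(traces: list[Trace], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {
                "time_h": t.time_h,
                "intensity": t.intensity,
                "trace_id": t.trace_id,
                "condition": t.condition,
                "channel": t.channel,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# generic tables with config metadata
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, config: PipelineConfig | None = None) -> Path:
    """Write a TSV preceded by ``# key=value`` metadata comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.config_hash()}\n")
            fh.write(f"# seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# umbrella pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    out_dir,
    matrix: ExpressionMatrix | None = None,
    matrix_path=None,
    dialect: str = "mtx",
    clusters_path=None,
) -> Path:
    """Load (or accept) a matrix, infer oscillators per cluster, intersect.

    Writes per-cluster pair tables, community tables and oscillator
    lists, the filter-cascade report, the shared/all/non-oscillator
    derivations, and a machine-readable run manifest. Any stage failure
    aborts with the stage name; outputs written so far are kept.
    """
    from .cooscillation import infer_oscillators
    from .genelists import derive_nonoscillators, shared_across, union_all
    from .preprocess import zero_filter

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    manifest: dict = {"config": config.to_dict(), "config_hash": config.config_hash()}
    try:
        if matrix is None:
            if matrix_path is None:
                raise FileNotFoundError("no matrix given: pass matrix or matrix_path")
            matrix = read_expression_matrix(matrix_path, dialect, clusters_path)
        manifest["n_genes"] = matrix.n_genes
        manifest["n_cells"] = matrix.n_cells

        stage = "infer"
        calls = []
        expressed_sets = []
        oscillator_sets = []
        reports = []
        for cluster in matrix.cluster_labels:
            if matrix.cluster_columns(cluster).size < config.min_cells:
                logger.warning("skipping cluster %r: fewer than min_cells", cluster)
                continue
            call = infer_oscillators(matrix, cluster, config)
            calls.append(call)
            reports.append(call.report.to_row())
            expressed_sets.append(
                GeneSet(f"expressed_{cluster}", zero_filter(matrix, cluster, config.zero_threshold))
            )
            oscillator_sets.append(GeneSet(f"oscillators_{cluster}", call.oscillators))
            write_table(call.pair_table, out / f"pairs_{cluster}.tsv", config)
            comm_rows = [
                {"community_id": i, "gene": g}
                for i, c in enumerate(call.communities)
                for g in sorted(c.genes)
            ]
            write_table(
                pd.DataFrame(comm_rows, columns=["community_id", "gene"]),
                out / f"communities_{cluster}.tsv", config,
            )
            write_gene_list(
                GeneSet("osc", call.oscillators), out / f"oscillators_{cluster}.txt"
            )
        if not calls:
            raise ValueError("no cluster had enough cells for inference")
        write_table(pd.DataFrame(reports), out / "filter_report.tsv", config)

        stage = "intersect"
        all_osc = union_all(oscillator_sets)
        write_gene_list(all_osc, out / "all_oscillators.txt")
        non_osc = derive_nonoscillators(expressed_sets, oscillator_sets)
        write_gene_list(non_osc, out / "non_oscillators.txt")
        if len(oscillator_sets) >= 2:
            shared = shared_across(oscillator_sets)
            write_gene_list(shared, out / "shared_oscillators.txt")
            manifest["n_shared_oscillators"] = len(shared)
        manifest["clusters"] = reports
        manifest["n_all_oscillators"] = len(all_osc)
        manifest["n_non_oscillators"] = len(non_osc)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
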
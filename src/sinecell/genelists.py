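"""Gene-list algebra and overlap statistics downstream of inference.

Covers the derivations an oscillator screen typically reports: the
union of oscillators over all clusters ("all oscillators"), the
intersection across sample groups ("shared oscillators"), expressed
genes never called oscillatory ("non-oscillators"), hypergeometric
overlap against a background universe, the fraction of a TF list
involved in dynamic network motifs, the low-cycling classification of a
cluster from its enrichment table, and candidate quiescence regulators
as a triple intersection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "OverlapResult",
    "GseaRecord",
    "CELL_CYCLE_HALLMARKS",
    "shared_across",
    "union_all",
    "derive_nonoscillators",
    "hypergeometric_overlap",
    "motif_fraction",
    "classify_low_cycling",
    "quiescence_candidates",
]


def _clean_symbols(genes: Iterable[str], uppercase: bool = False) -> frozenset:
    out = set()
    for g in genes:
        g = str(g).strip()
        if not g:
            raise ValueError("empty gene symbol")
        out.add(g.upper() if uppercase else g)
    return frozenset(out)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (whitespace-trimmed, case-sensitive).

    Pass ``uppercase=True`` to normalize symbols for human HGNC-style
    lists where mixed-case aliases would otherwise silently mismatch.
    """

    name: str
    genes: frozenset

    def __init__(self, name: str, genes: Iterable[str], uppercase: bool = False):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", _clean_symbols(genes, uppercase))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def intersection(self, *others: "GeneSet", name: str = "intersection") -> "GeneSet":
        genes = self.genes
        for o in others:
            genes = genes & o.genes
        return GeneSet(name, genes)

    def union(self, *others: "GeneSet", name: str = "union") -> "GeneSet":
        genes = self.genes
        for o in others:
            genes = genes | o.genes
        return GeneSet(name, genes)

    def difference(self, other: "GeneSet", name: str = "difference") -> "GeneSet":
        return GeneSet(name, self.genes - other.genes)


@dataclass
class OverlapResult:
    """Upper-tail hypergeometric overlap of two sets in a background."""

    overlap_count: int
    set_a_size: int
    set_b_size: int
    background_size: int
    p_hypergeometric: float
    fold_enrichment: float


@dataclass
class GseaRecord:
    """One row of a per-cluster gene-set enrichment table."""

    cluster: object
    gene_set_name: str
    direction: str  # "up" | "down"
    adjusted_p: float
    rank_within_direction: int

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError("direction must be 'up' or 'down'")
        if self.rank_within_direction < 1:
            raise ValueError("rank must be >= 1")
        if not 0 < self.adjusted_p <= 1:
            raise ValueError("adjusted_p must be in (0, 1]")


#: Hallmark gene sets whose downregulation marks a low-cycling cluster.
CELL_CYCLE_HALLMARKS = frozenset({"E2F Targets", "G2M Checkpoint", "Mitotic Spindle"})


def _as_genesets(groups: Sequence) -> list[GeneSet]:
    """Normalize a list of GeneSet or list-of-GeneSet (per-group union)."""
    out = []
    for i, item in enumerate(groups):
        if isinstance(item, GeneSet):
            out.append(item)
        else:
            inner = list(item)
            if not inner:
                raise ValueError("empty sub-group of gene sets")
            out.append(inner[0].union(*inner[1:], name=f"group_{i}"))
    return out


def shared_across(per_group_oscillators: Sequence) -> GeneSet:
    """Genes oscillatory in every group (e.g. every tumour).

    Each element is either a GeneSet (one group's oscillators) or a
    sequence of GeneSets (one group's subclusters, unioned first); the
    result is the intersection across groups.
    """
    if not per_group_oscillators:
        raise ValueError("need at least one group of oscillator sets")
    sets = _as_genesets(per_group_oscillators)
    if len(sets) < 2:
        raise ValueError("shared_across needs at least two groups")
    return sets[0].intersection(*sets[1:], name="shared_oscillators")


def union_all(per_group_oscillators: Sequence) -> GeneSet:
    """Deduplicated union over all groups ("all oscillators")."""
    if not per_group_oscillators:
        raise ValueError("need at least one gene set")
    sets = _as_genesets(per_group_oscillators)
    return sets[0].union(*sets[1:], name="all_oscillators")


def derive_nonoscillators(
    expressed_sets: Sequence, oscillator_sets: Sequence
) -> GeneSet:
    """Genes expressed in at least one group but never called oscillatory."""
    expressed = union_all(expressed_sets) if expressed_sets else GeneSet("expressed", [])
    oscillators = union_all(oscillator_sets) if oscillator_sets else GeneSet("osc", [])
    return GeneSet("non_oscillators", expressed.genes - oscillators.genes)


def hypergeometric_overlap(
    set_a: GeneSet, set_b: GeneSet, background: GeneSet
) -> OverlapResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    With N background genes, K in A, n in B and k = |A & B| the p-value
    is ``P(X >= k)`` for X hypergeometric(N, K, n) — the probability of
    at least the observed overlap when B is drawn at random from the
    background. Symbols outside the background are dropped with a
    warning. ``fold_enrichment = (k/n) / (K/N)``.
    """
    if len(background) == 0:
        raise ValueError("background set is empty")
    a = set_a.genes & background.genes
    b = set_b.genes & background.genes
    stray = (set_a.genes | set_b.genes) - background.genes
    if stray:
        logger.warning(
            "hypergeometric_overlap: dropping %d symbols absent from the "
            "background (e.g. %s)", len(stray), sorted(stray)[:5],
        )
    N, K, n = len(background), len(a), len(b)
    k = len(a & b)
    # survival function at k-1 gives P(X >= k); scipy evaluates in log space
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, math.ulp(0.0)), 1.0)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return OverlapResult(
        overlap_count=k,
        set_a_size=K,
        set_b_size=n,
        background_size=N,
        p_hypergeometric=p,
        fold_enrichment=fold,
    )


def motif_fraction(
    tf_set: GeneSet, motif_tfs: GeneSet, evaluable_tfs: GeneSet
) -> float | None:
    """Percentage of a TF list's evaluable members found in dynamic motifs.

    Only TFs for which motif membership could be assessed (the
    ``evaluable_tfs`` catalogue) enter the denominator. Returns None
    when no member of ``tf_set`` is evaluable.
    """
    if not motif_tfs.genes <= evaluable_tfs.genes:
        raise ValueError("motif_tfs must be a subset of evaluable_tfs")
    evaluable = tf_set.genes & evaluable_tfs.genes
    if not evaluable:
        return None
    in_motif = tf_set.genes & motif_tfs.genes
    return 100.0 * len(in_motif) / len(evaluable)


def classify_low_cycling(
    records: Sequence[GseaRecord],
    significance_cutoff: float = 0.1,
    top_n: int = 3,
) -> bool:
    """Is a cluster low-cycling, judged from its enrichment table?

    True iff any cell-cycle Hallmark set (E2F Targets, G2M Checkpoint,
    Mitotic Spindle) is significantly enriched among the downregulated
    sets (adjusted p < cutoff) within the top ``top_n`` downregulated
    ranks.
    """
    clusters = {r.cluster for r in records}
    if len(clusters) > 1:
        raise ValueError(f"records span multiple clusters: {sorted(map(str, clusters))}")
    for r in records:
        if (
            r.gene_set_name in CELL_CYCLE_HALLMARKS
            and r.direction == "down"
            and r.adjusted_p < significance_cutoff
            and r.rank_within_direction <= top_n
        ):
            return True
    return False


def quiescence_candidates(
    shared: GeneSet, tf_catalogue: GeneSet, neural_g0: GeneSet
) -> GeneSet:
    """Shared oscillators that are TFs and carry a quiescence signature."""
    return GeneSet(
        "quiescence_candidates",
        shared.genes & tf_catalogue.genes & neural_g0.genes,
    )
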
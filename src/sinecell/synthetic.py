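"""Synthetic data with planted ground truth.

Three generators feed the downstream stages:

* :func:`generate_cosc_matrix` — an expression matrix in which groups of
  genes co-oscillate as phase-shifted sinusoids of a shared latent cell
  phase, on top of non-oscillatory noise genes, with entrywise dropout.
  Cells are unsynchronized: each cell sits at an independent uniform
  phase of the latent cycle, so no cell ordering carries information.
* :func:`generate_trace` — a fluorescence reporter time series with a
  known period, an optional slow trend, noise, and optionally thinned
  (unevenly sampled) time points.
* :func:`generate_genelist_fixture` — named gene sets over a synthetic
  symbol universe with an exactly controlled pairwise overlap.

Defaults emulate the regimes the pipeline is meant for: a few hundred
cells per cluster, a planted group of ~20 co-oscillating genes against a
~10x larger noise background at signal-to-noise (amplitude / noise SD) 4
and 10% dropout; imaging traces of roughly three days sampled every
20 minutes with an ultradian (< 24 h) period.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .periodicity import Trace

__all__ = [
    "OscillatorGroupSpec",
    "SyntheticMatrixSpec",
    "GroundTruth",
    "SyntheticTraceSpec",
    "generate_cosc_matrix",
    "generate_trace",
    "generate_genelist_fixture",
]


@dataclass
class OscillatorGroupSpec:
    """One group of co-oscillating genes sharing a latent frequency.

    ``relative_frequency`` counts cycles per revolution of the latent
    cell phase; genes inside the group differ only by phase, drawn
    uniformly from ``[0, phase_dispersion)``.
    """

    n_genes: int = 20
    relative_frequency: float = 1.0
    amplitude: float = 2.0
    phase_dispersion: float = 2 * math.pi

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a co-oscillation group needs n_genes >= 2")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.relative_frequency <= 0:
            raise ValueError("relative_frequency must be positive")
        if not 0 <= self.phase_dispersion <= 2 * math.pi:
            raise ValueError("phase_dispersion must be in [0, 2*pi]")


@dataclass
class SyntheticMatrixSpec:
    """Recipe for a planted co-oscillation expression matrix."""

    n_cells: int = 300
    groups: list[OscillatorGroupSpec] = field(
        default_factory=lambda: [OscillatorGroupSpec()]
    )
    n_noise_genes: int = 180
    baseline_mean: float = 2.5
    noise_sd: float = 0.5
    dropout_rate: float = 0.1
    seed: int = 0
    cluster_label: str = "c0"

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if self.n_noise_genes + sum(g.n_genes for g in self.groups) == 0:
            raise ValueError("spec describes no genes at all")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic matrix.

    ``genes`` has one row per gene: label ('oscillator' | 'noise'),
    group id (-1 for noise) and true phase (NaN for noise).
    ``latent_phase`` is the per-cell phase theta_s in [0, 2*pi).
    ``clip_rate`` is the fraction of pre-dropout entries clipped at 0.
    """

    genes: pd.DataFrame
    latent_phase: np.ndarray
    clip_rate: float

    @property
    def oscillator_genes(self) -> set[str]:
        mask = self.genes["label"] == "oscillator"
        return set(self.genes.index[mask])

    @property
    def noise_genes(self) -> set[str]:
        mask = self.genes["label"] == "noise"
        return set(self.genes.index[mask])


def generate_cosc_matrix(spec: SyntheticMatrixSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate an unsynchronized population with planted co-oscillators.

    For an oscillator gene g in group k with phase phi_g, the pre-dropout
    value in cell s is::

        max(0, baseline_mean + amplitude_k * sin(f_k * theta_s + phi_g) + N(0, noise_sd))

    with theta_s ~ Uniform[0, 2*pi) independently per cell. Noise genes
    omit the sinusoid. Every entry is then zeroed independently with
    probability ``dropout_rate``. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    theta = rng.uniform(0.0, 2 * math.pi, size=spec.n_cells)

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    labels: list[str] = []
    group_ids: list[int] = []
    phases: list[float] = []

    for k, grp in enumerate(spec.groups):
        phi = rng.uniform(0.0, grp.phase_dispersion or 0.0, size=grp.n_genes) \
            if grp.phase_dispersion > 0 else np.zeros(grp.n_genes)
        for j in range(grp.n_genes):
            signal = grp.amplitude * np.sin(grp.relative_frequency * theta + phi[j])
            rows.append(spec.baseline_mean + signal)
            gene_ids.append(f"OSC{k}_{j:03d}")
            labels.append("oscillator")
            group_ids.append(k)
            phases.append(float(phi[j]))
    for j in range(spec.n_noise_genes):
        rows.append(np.full(spec.n_cells, spec.baseline_mean))
        gene_ids.append(f"NOISE_{j:03d}")
        labels.append("noise")
        group_ids.append(-1)
        phases.append(float("nan"))

    values = np.stack(rows)
    values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    clip_rate = float(np.mean(values < 0))
    np.maximum(values, 0.0, out=values)
    if spec.dropout_rate > 0:
        keep = rng.random(values.shape) >= spec.dropout_rate
        values = values * keep

    cell_ids = [f"cell_{s:04d}" for s in range(spec.n_cells)]
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        clusters=pd.Series(spec.cluster_label, index=cell_ids),
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {"label": labels, "group": group_ids, "phase": phases}, index=gene_ids
        ),
        latent_phase=theta,
        clip_rate=clip_rate,
    )
    return matrix, truth


@dataclass
class SyntheticTraceSpec:
    """Recipe for a single fluorescence trace with a known period."""

    period_h: float = 17.0
    duration_h: float = 70.0
    sampling_interval_h: float = 1 / 3
    amplitude: float = 100.0
    offset: float = 500.0
    trend_type: str = "linear"  # none | linear | slow-sinusoid
    trend_slope: float = 2.0  # a.u. per hour (linear) / amplitude scale (slow-sinusoid)
    noise_sd: float = 20.0
    drop_fraction: float = 0.0
    seed: int = 0
    trace_id: str = "trace0"
    condition: str = "proliferative"
    channel: str = "signal"

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be positive")
        if self.trend_type not in {"none", "linear", "slow-sinusoid"}:
            raise ValueError("trend_type must be none|linear|slow-sinusoid")
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.offset <= 0:
            raise ValueError("offset must be positive")


def _trend(spec: SyntheticTraceSpec, t: np.ndarray) -> np.ndarray:
    if spec.trend_type == "linear":
        return spec.trend_slope * t
    if spec.trend_type == "slow-sinusoid":
        # one slow cycle over the full duration
        return spec.trend_slope * spec.duration_h / 4 * np.sin(2 * math.pi * t / spec.duration_h)
    return np.zeros_like(t)


def generate_trace(spec: SyntheticTraceSpec) -> Trace:
    """Simulate ``offset + amplitude*sin(2*pi*t/period) + trend + noise``.

    Time points run 0..duration in steps of the sampling interval and are
    optionally thinned at ``drop_fraction`` to create uneven sampling
    (the first and last samples are always kept so the duration is
    preserved). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(math.floor(spec.duration_h / spec.sampling_interval_h)) + 1
    t = np.arange(n) * spec.sampling_interval_h
    if spec.drop_fraction > 0:
        keep = rng.random(n) >= spec.drop_fraction
        keep[0] = keep[-1] = True
        t = t[keep]
    intensity = (
        spec.offset
        + spec.amplitude * np.sin(2 * math.pi * t / spec.period_h)
        + _trend(spec, t)
        + rng.normal(0.0, spec.noise_sd, size=t.size)
    )
    return Trace(
        time_h=t,
        intensity=intensity,
        trace_id=spec.trace_id,
        condition=spec.condition,
        channel=spec.channel,
    )


def generate_genelist_fixture(
    universe_size: int,
    set_sizes: tuple[int, ...],
    forced_overlap: int,
    seed: int = 0,
    names: tuple[str, ...] | None = None,
):
    """Named gene sets over a synthetic universe with exact overlap.

    The first two sets share exactly ``forced_overlap`` symbols; any
    further sets are drawn uniformly from the universe. Returns
    ``(sets, universe)`` where ``sets`` is a list of
    :class:`~sinecell.genelists.GeneSet`.
    """
    from .genelists import GeneSet

    if len(set_sizes) < 2:
        raise ValueError("need at least two set sizes")
    if forced_overlap > min(set_sizes[:2]):
        raise ValueError("forced_overlap exceeds the smaller of the first two sets")
    if max(set_sizes) > universe_size:
        raise ValueError("set size exceeds universe")
    n_a, n_b = set_sizes[0], set_sizes[1]
    if n_a + n_b - forced_overlap > universe_size:
        raise ValueError("universe too small for the requested overlap structure")

    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)
    shared = perm[:forced_overlap]
    only_a = perm[forced_overlap : forced_overlap + (n_a - forced_overlap)]
    only_b = perm[
        forced_overlap + (n_a - forced_overlap) : n_a + n_b - forced_overlap
    ]
    if names is None:
        names = tuple(f"set_{i}" for i in range(len(set_sizes)))
    sets = [
        GeneSet(names[0], {universe[i] for i in np.concatenate([shared, only_a])}),
        GeneSet(names[1], {universe[i] for i in np.concatenate([shared, only_b])}),
    ]
    for extra_idx, size in enumerate(set_sizes[2:], start=2):
        pick = rng.choice(universe_size, size=size, replace=False)
        sets.append(GeneSet(names[extra_idx], {universe[i] for i in pick}))
    full_universe = GeneSet("universe", set(universe))
    return sets, full_universe
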
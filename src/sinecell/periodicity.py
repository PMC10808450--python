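"""Periodicity analysis of single-cell fluorescence reporter traces.

The analysis mirrors the standard workflow for detecting ultradian
(< 24 h) oscillations in live-imaging intensity tracks:

1. QC: drop traces that are too short to resolve a sub-daily period and
   cohort-level variance outliers.
2. Detrend with a Gaussian-weighted moving average (24 h window), which
   removes slow drifts (photobleaching, expression-level trends) while
   retaining sub-daily fluctuations.
3. Lomb-Scargle power spectral density on the detrended trace — the
   classical periodogram for unevenly sampled series — over a period
   band of 2-24 h.
4. Dominant power = peak PSD; dominant period = 1 / peak frequency.
5. Per-condition summary: periodograms interpolated onto a common
   frequency grid and averaged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

__all__ = [
    "Trace",
    "DetrendResult",
    "Periodogram",
    "ConditionSummary",
    "qc_filter_traces",
    "gaussian_detrend",
    "lomb_scargle_psd",
    "common_grid_average",
    "summarize_condition",
]


@dataclass
class Trace:
    """A time-stamped fluorescence intensity series for one cell."""

    time_h: np.ndarray
    intensity: np.ndarray
    trace_id: str = "trace"
    condition: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_h.size != self.intensity.size:
            raise ValueError("time_h and intensity must have equal length")
        if self.time_h.size < 3:
            raise ValueError("a trace needs at least 3 samples")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if np.any(~np.isfinite(self.intensity)):
            raise ValueError("intensity contains missing values")

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])


@dataclass
class DetrendResult:
    """Trend and residual; ``trend + detrended`` reconstructs the input."""

    trend: np.ndarray
    detrended: np.ndarray


@dataclass
class Periodogram:
    """Lomb-Scargle PSD on an increasing frequency grid (cycles/hour)."""

    frequency: np.ndarray
    power: np.ndarray
    normalization: str = "normalized"

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def dominant_power(self) -> float:
        return float(np.max(self.power))

    @property
    def dominant_period_h(self) -> float:
        return float(1.0 / self.frequency[int(np.argmax(self.power))])


@dataclass
class ConditionSummary:
    """Per-condition aggregate of QC, per-trace peaks and the mean PSD."""

    condition: str
    per_trace: pd.DataFrame
    frequency: np.ndarray | None
    mean_psd: np.ndarray | None
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.per_trace)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def qc_filter_traces(
    traces: list[Trace],
    min_duration_h: float = 25.0,
    variance_sds: float = 5.0,
) -> tuple[list[Trace], list[tuple[str, str]]]:
    """Exclude traces that are too short or cohort variance outliers.

    A trace is dropped when its duration is strictly below
    ``min_duration_h`` (a trace of exactly the minimum duration is kept),
    or when its intensity variance exceeds the cohort mean variance by
    more than ``variance_sds`` standard deviations of the cohort's trace
    variances. Both reasons are recorded per excluded trace.
    """
    if not traces:
        return [], []
    variances = np.array([float(np.var(t.intensity, ddof=1)) for t in traces])
    mean_v = variances.mean()
    sd_v = variances.std(ddof=1) if len(variances) > 1 else 0.0
    cutoff = mean_v + variance_sds * sd_v
    kept: list[Trace] = []
    excluded: list[tuple[str, str]] = []
    for trace, v in zip(traces, variances):
        if trace.duration_h < min_duration_h:
            excluded.append((trace.trace_id, "duration"))
        elif sd_v > 0 and v > cutoff:
            excluded.append((trace.trace_id, "variance"))
        else:
            kept.append(trace)
    return kept, excluded


def gaussian_detrend(trace: Trace, window_h: float = 24.0) -> DetrendResult:
    """Gaussian-weighted moving-average trend, subtracted from the trace.

    The trend at time t_k is the weighted mean of intensities with
    weights ``exp(-(t_j - t_k)^2 / (2 sigma^2))``, sigma = window/5,
    truncated at ``|t_j - t_k| <= window/2``. A 24 h window suppresses
    fluctuations slower than a day while passing ultradian components.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    t = trace.time_h
    sigma = window_h / 5.0
    half = window_h / 2.0
    dt = t[None, :] - t[:, None]
    w = np.exp(-(dt**2) / (2 * sigma**2))
    w[np.abs(dt) > half] = 0.0
    trend = (w @ trace.intensity) / w.sum(axis=1)
    return DetrendResult(trend=trend, detrended=trace.intensity - trend)


def lomb_scargle_psd(
    detrended: np.ndarray,
    time_h: np.ndarray,
    band: tuple[float, float] = (2.0, 24.0),
    oversample: int = 4,
) -> Periodogram:
    """Variance-normalized Lomb-Scargle PSD over a period band.

    The frequency grid spans ``1/band_max .. 1/band_min`` cycles/hour at
    a spacing of ``1 / (oversample * duration)``, the natural spectral
    resolution refined by the oversampling factor. Works on unevenly
    sampled series; deterministic.
    """
    time_h = np.asarray(time_h, dtype=float)
    detrended = np.asarray(detrended, dtype=float)
    if time_h.size < 3:
        raise ValueError("need at least 3 samples")
    lo_period, hi_period = band
    duration = time_h[-1] - time_h[0]
    if duration <= lo_period:
        raise ValueError(
            f"trace duration {duration:.2f} h cannot resolve periods down to "
            f"{lo_period} h"
        )
    median_dt = float(np.median(np.diff(time_h)))
    if lo_period < 2 * median_dt:
        raise ValueError(
            f"shortest requested period {lo_period} h is below the Nyquist "
            f"limit {2 * median_dt:.2f} h for this sampling"
        )
    f_lo, f_hi = 1.0 / hi_period, 1.0 / lo_period
    df = 1.0 / (oversample * duration)
    freqs = np.arange(f_lo, f_hi + df / 2, df)
    power = lombscargle(
        time_h, detrended - detrended.mean(), 2 * np.pi * freqs, normalize=True
    )
    return Periodogram(frequency=freqs, power=power)


def common_grid_average(periodograms: list[Periodogram]) -> Periodogram:
    """Mean PSD after linear interpolation onto a shared frequency grid.

    The grid covers the intersection of all input bands at the finest
    input resolution, so every input contributes everywhere.
    """
    if not periodograms:
        raise ValueError("need at least one periodogram")
    lo = max(p.frequency[0] for p in periodograms)
    hi = min(p.frequency[-1] for p in periodograms)
    if lo >= hi:
        raise ValueError("periodogram frequency bands are disjoint")
    df = min(float(np.min(np.diff(p.frequency))) for p in periodograms)
    grid = np.arange(lo, hi + df / 2, df)
    stacked = np.stack([np.interp(grid, p.frequency, p.power) for p in periodograms])
    return Periodogram(frequency=grid, power=stacked.mean(axis=0))


def summarize_condition(
    traces: list[Trace],
    condition: str,
    min_duration_h: float = 25.0,
    window_h: float = 24.0,
    band: tuple[float, float] = (2.0, 24.0),
    oversample: int = 4,
) -> ConditionSummary:
    """QC -> detrend -> periodogram per trace, then aggregate.

    Returns per-trace dominant power/period and mean raw intensity for
    the QC-passing traces, plus the mean PSD on a common grid.
    """
    cohort = [t for t in traces if t.condition == condition or condition == ""]
    kept, excluded = qc_filter_traces(cohort, min_duration_h=min_duration_h)
    rows = []
    pgrams = []
    for trace in kept:
        det = gaussian_detrend(trace, window_h=window_h)
        pg = lomb_scargle_psd(det.detrended, trace.time_h, band=band, oversample=oversample)
        pgrams.append(pg)
        rows.append(
            {
                "trace_id": trace.trace_id,
                "condition": trace.condition,
                "channel": trace.channel,
                "duration_h": trace.duration_h,
                "variance": float(np.var(trace.intensity, ddof=1)),
                "dominant_power": pg.dominant_power,
                "dominant_period_h": pg.dominant_period_h,
                "mean_intensity": float(trace.intensity.mean()),
            }
        )
    per_trace = pd.DataFrame(
        rows,
        columns=[
            "trace_id",
            "condition",
            "channel",
            "duration_h",
            "variance",
            "dominant_power",
            "dominant_period_h",
            "mean_intensity",
        ],
    )
    if pgrams:
        mean_pg = common_grid_average(pgrams)
        frequency, mean_psd = mean_pg.frequency, mean_pg.power
    else:
        warnings.warn(f"all traces excluded for condition {condition!r}")
        frequency, mean_psd = None, None
    return ConditionSummary(
        condition=condition,
        per_trace=per_trace,
        frequency=frequency,
        mean_psd=mean_psd,
        excluded=excluded,
    )
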
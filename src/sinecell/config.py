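"""Pipeline configuration: defaults, validation, flat-file serialization."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig", "read_config", "write_config"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the inference and periodicity pipelines.

    Attributes
    ----------
    zero_threshold
        Minimum fraction of a cluster's cells in which a gene must be
        non-zero to pass the zero-filter (inclusive).
    alpha
        FDR level for calling significant co-oscillating pairs.
    n_perm
        Number of pooled permutation draws for the null distribution.
    psi_grid_points
        Grid resolution for the phase-shift minimization on [0, pi].
    seed
        Seed for every stochastic step (permutations, simulation).
    log_transform
        Apply log1p to expression before the pair statistic.
    window_h
        Width of the Gaussian detrending window, hours.
    min_duration_h
        Traces shorter than this (hours) are excluded by QC.
    band
        (shortest, longest) period in hours searched by the periodogram.
    min_cells
        Minimum cells a cluster needs before inference is attempted.
    oversample
        Frequency-grid oversampling factor for the periodogram.
    """

    zero_threshold: float = 0.8
    alpha: float = 0.05
    n_perm: int = 1000
    psi_grid_points: int = 1000
    seed: int = 0
    log_transform: bool = False
    window_h: float = 24.0
    min_duration_h: float = 25.0
    band: tuple[float, float] = (2.0, 24.0)
    min_cells: int = 20
    oversample: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.zero_threshold <= 1:
            raise ValueError("zero_threshold must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.psi_grid_points < 2:
            raise ValueError("psi_grid_points must be >= 2")
        if self.window_h <= 0:
            raise ValueError("window_h must be positive")
        if self.min_duration_h < 0:
            raise ValueError("min_duration_h must be >= 0")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < shortest < longest period")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for output metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "band":
        lo, hi = raw.split(":")
        return (float(lo), float(hi))
    if key == "log_transform":
        if raw.lower() in {"true", "1", "yes"}:
            return True
        if raw.lower() in {"false", "0", "no"}:
            return False
        raise ValueError(f"cannot parse boolean {raw!r} for {key}")
    if key in {"n_perm", "psi_grid_points", "seed", "min_cells", "oversample"}:
        return int(raw)
    return float(raw)


def read_config(path) -> PipelineConfig:
    """Read a flat ``key = value`` text file; unknown keys are errors."""
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = _parse_value(key, raw)
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path) -> None:
    lines = []
    for key, value in config.to_dict().items():
        if key == "band":
            value = f"{value[0]}:{value[1]}"
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
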
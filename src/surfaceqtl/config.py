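"""Pipeline configuration: a validated, YAML-serializable settings object.

A fully default :class:`PipelineConfig` reproduces the standard pipeline
(simulate an 89-line population under the nine-combination design, scan
with kinship weighting and a 5-marker Simes window at alpha 0.05, fit
producing functions on relative meshes, and compare shapes) with no other
input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import InvalidArgumentError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # input paths; None means "simulate instead of read"
    genotype_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    kinship_path: str | None = None
    surfaces_path: str | None = None  # optional table of quadratic coefficients

    # evaluation grid
    water_interval: tuple[float, float] = (-42.0, 42.0)
    nitrogen_interval: tuple[float, float] = (-7.5, 7.5)
    grid_step: float = 0.5

    # simulation
    n_lines: int = 89
    n_chromosomes: int = 10
    markers_per_chromosome: int = 20
    chromosome_length_cm: float = 120.0
    expansion_factor: float = 4.0
    missing_rate: float = 0.0
    water_levels: tuple[float, ...] = (8.0, 20.0, 50.0, 80.0, 92.0)
    nitrogen_levels: tuple[float, ...] = (0.0, 2.5, 7.5, 12.5, 15.0)
    corner_reps: int = 4
    center_reps: int = 8
    baseline_cm: float = 30.0
    sigma_line: float = 2.0
    sigma_resid: float = 3.0
    causal_marker: str | None = "m05_010"  # None disables the planted QTL

    # scan
    simes_window: int = 5
    alpha: float = 0.05
    methods: tuple[str, ...] = ("sidak", "fdr")
    min_class_obs: int = 10

    # meshes / shape comparison
    points_per_ray: int = 10
    exclusion_margin: float = 0.10

    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = [
            (self.grid_step > 0, "grid_step must be positive"),
            (self.n_lines >= 2, "n_lines must be >= 2"),
            (self.n_chromosomes >= 1, "n_chromosomes must be >= 1"),
            (self.markers_per_chromosome >= 2, "markers_per_chromosome must be >= 2"),
            (self.expansion_factor > 0, "expansion_factor must be positive"),
            (0 <= self.missing_rate < 1, "missing_rate must be in [0, 1)"),
            (self.corner_reps > 0 and self.center_reps > 0, "replicates must be positive"),
            (self.sigma_line >= 0 and self.sigma_resid >= 0, "sigmas must be >= 0"),
            (self.simes_window >= 1 and self.simes_window % 2 == 1,
             "simes_window must be a positive odd integer"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.min_class_obs >= 0, "min_class_obs must be >= 0"),
            (self.points_per_ray >= 2, "points_per_ray must be >= 2"),
            (self.exclusion_margin >= 0, "exclusion_margin must be >= 0"),
            (all(m in ("sidak", "fdr") for m in self.methods),
             "methods must be among sidak, fdr"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidArgumentError(msg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        for key in ("water_interval", "nitrogen_interval", "water_levels",
                    "nitrogen_levels", "methods"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
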
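"""Pipeline configuration: dataclasses, YAML loading, strict validation.

Every tunable of the simulate → prep → heights → compare → h2 → attribute
chain lives here with its default.  ``validate_config`` loads a YAML mapping,
rejects unknown keys, checks ranges, and either returns a fully resolved
:class:`PipelineConfig` or raises :class:`ConfigError` listing *every*
violation (nothing is silently corrected).  ``config_to_dict`` round-trips the
resolved config into the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic_field import (
    DEFAULT_STAGES,
    FMObservationModel,
    SensorModel,
    default_sensors,
    gls_max_detectable,
)

__all__ = ["SimulationConfig", "PrepConfig", "MetricsConfig", "CompareConfig",
           "H2Config", "AttributionConfig", "IOConfig", "PipelineConfig",
           "validate_config", "config_to_dict", "config_from_dict"]


def _default_stage_means() -> dict:
    return {"jointing": 0.55, "heading": 0.72, "flowering": 0.85, "maturity": 0.82}


@dataclass
class SimulationConfig:
    """Synthetic-trial parameters; defaults mirror the 480-plot wheat trial."""

    g: int = 120
    e: int = 2
    r_reps: int = 2
    stages: list = field(default_factory=lambda: list(DEFAULT_STAGES))
    stage_means: dict = field(default_factory=_default_stage_means)
    plot_side: float = 1.0
    plot_spacing: float = 0.5
    var_G: float = 0.010
    var_E: float = 0.002
    var_GE: float = 0.002
    var_eps: float = 0.004
    unevenness: float = 0.35
    cover_fraction: float = 0.85
    resolution: float = 0.01
    density_scale: float = 2e-3
    density_floor: float = 800.0
    gls_scan_range: float = 1.1
    gls_ground_filter: float = 0.28
    fm_k_locations: int = 3
    fm_window_side: float = 0.3
    fm_observer_sd: float = 0.02
    lai_alpha: float = 5.0
    lai_noise_sd: float = 0.3
    alley_ground_fraction: float = 0.25
    terrain_slope_x: float = 0.0
    terrain_slope_y: float = 0.0
    sensor_names: list = field(default_factory=lambda: ["TLS", "BLS", "GLS", "DAP"])

    def sensors(self) -> dict[str, SensorModel]:
        all_sensors = default_sensors(
            density_scale=self.density_scale,
            density_floor=self.density_floor,
            gls_ground_filter=self.gls_ground_filter,
            gls_scan_range=self.gls_scan_range,
        )
        return {name: all_sensors[name] for name in self.sensor_names}

    def fm_model(self) -> FMObservationModel:
        return FMObservationModel(
            k_locations=self.fm_k_locations,
            window_side=self.fm_window_side,
            observer_sd=self.fm_observer_sd,
        )

    def terrain(self):
        sx, sy = self.terrain_slope_x, self.terrain_slope_y
        if sx == 0.0 and sy == 0.0:
            return 0.0
        return lambda x, y: sx * x + sy * y

    def problems(self) -> list[str]:
        p = []
        if self.g < 1 or self.e < 1 or self.r_reps < 1:
            p.append("simulation: g, e, r_reps must all be >= 1")
        if not self.stages:
            p.append("simulation: at least one stage required")
        missing = [s for s in self.stages if s not in self.stage_means]
        if missing:
            p.append(f"simulation: stage_means missing entries for {missing}")
        if any(v <= 0 for v in self.stage_means.values()):
            p.append("simulation: stage_means must be positive")
        if not 0.0 < self.cover_fraction <= 1.0:
            p.append("simulation: cover_fraction must be in (0, 1]")
        if self.unevenness < 0:
            p.append("simulation: unevenness must be >= 0")
        for nm in ("var_G", "var_E", "var_GE", "var_eps"):
            if getattr(self, nm) < 0:
                p.append(f"simulation: {nm} must be >= 0")
        if self.resolution <= 0 or self.resolution > self.plot_side:
            p.append("simulation: resolution must be in (0, plot_side]")
        if self.density_scale <= 0 or self.density_floor <= 0:
            p.append("simulation: density_scale and density_floor must be > 0")
        if self.gls_scan_range <= self.gls_ground_filter:
            p.append("simulation: gls_scan_range must exceed gls_ground_filter")
        if self.fm_window_side <= 0 or self.fm_window_side > self.plot_side:
            p.append("simulation: fm_window_side must be in (0, plot_side]")
        if self.fm_observer_sd < 0:
            p.append("simulation: fm_observer_sd must be >= 0")
        bad_sensors = set(self.sensor_names) - {"TLS", "BLS", "GLS", "DAP"}
        if bad_sensors or not self.sensor_names:
            p.append(f"simulation: sensor_names must be a non-empty subset of TLS/BLS/GLS/DAP"
                     f" (got {self.sensor_names})")
        return p


@dataclass
class PrepConfig:
    cell_size: float = 0.5
    z_tolerance: float = 0.05
    denoise_k: int = 10
    denoise_sd: float = 3.0
    run_denoise: bool = True
    #: trust the generator's flat, already-leveled ground: skip ground
    #: filtering and treat z as height above ground directly
    assume_flat_ground: bool = False

    def problems(self) -> list[str]:
        p = []
        if self.cell_size <= 0:
            p.append("prep: cell_size must be > 0")
        if self.z_tolerance < 0:
            p.append("prep: z_tolerance must be >= 0")
        if self.denoise_k < 1:
            p.append("prep: denoise_k must be >= 1")
        return p


@dataclass
class MetricsConfig:
    #: percentile estimator handed to numpy (the plotting-position rule)
    quantile_method: str = "linear"

    def problems(self) -> list[str]:
        valid = {"linear", "lower", "higher", "nearest", "midpoint"}
        return [] if self.quantile_method in valid else [
            f"metrics: quantile_method must be one of {sorted(valid)}"
        ]


@dataclass
class CompareConfig:
    ch_edges: list = field(default_factory=lambda: [0.3, 0.6, 0.8, 1.0, 1.4])
    lai_edges: list = field(default_factory=lambda: [0.0, 2.0, 4.0, 6.0, 8.0])
    #: None -> derived from the GLS scan-range arithmetic (1.1 - 0.28 = 0.82)
    gls_ceiling: float | None = None

    def resolved_ceiling(self, sim: SimulationConfig) -> float:
        if self.gls_ceiling is not None:
            return self.gls_ceiling
        return gls_max_detectable(sim.gls_scan_range, sim.gls_ground_filter)

    def problems(self) -> list[str]:
        p = []
        for nm, edges in (("ch_edges", self.ch_edges), ("lai_edges", self.lai_edges)):
            if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
                p.append(f"compare: {nm} must be >= 2 strictly increasing values")
        if self.gls_ceiling is not None and self.gls_ceiling <= 0:
            p.append("compare: gls_ceiling must be > 0")
        return p


@dataclass
class H2Config:
    restrict_all_sources: bool = False
    min_varieties: int = 2
    ems_correction: bool = False

    def problems(self) -> list[str]:
        return [] if self.min_varieties >= 2 else ["h2: min_varieties must be >= 2"]


@dataclass
class AttributionConfig:
    tau: float = 0.2
    relaxed_m: int = 3

    def problems(self) -> list[str]:
        p = []
        if self.tau <= 0:
            p.append("attribution: tau must be > 0")
        if not 1 <= self.relaxed_m <= 4:
            p.append("attribution: relaxed_m must be in 1..4")
        return p


@dataclass
class IOConfig:
    write_clouds: bool = False
    cloud_format: str = "xyz"

    def problems(self) -> list[str]:
        return [] if self.cloud_format in {"xyz", "las"} else [
            "io: cloud_format must be 'xyz' or 'las'"
        ]


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    h2: H2Config = field(default_factory=H2Config)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def problems(self) -> list[str]:
        p = []
        for section in (self.simulation, self.prep, self.metrics, self.compare,
                        self.h2, self.attribution, self.io):
            p.extend(section.problems())
        return p


_SECTIONS = {
    "simulation": SimulationConfig,
    "prep": PrepConfig,
    "metrics": MetricsConfig,
    "compare": CompareConfig,
    "h2": H2Config,
    "attribution": AttributionConfig,
    "io": IOConfig,
}


def _build_section(cls, data: dict, section: str, problems: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        problems.append(f"{section}: unknown key(s) {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        problems.append(f"{section}: {exc}")
        return cls()


def config_from_dict(data: dict) -> PipelineConfig:
    """Build and validate a PipelineConfig from a plain mapping."""
    problems: list[str] = []
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        problems.append(f"top level: unknown key(s) {sorted(unknown)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            problems.append(f"{name}: expected a mapping")
            sub = {}
        sections[name] = _build_section(cls, sub, name, problems)
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed must be an integer")
        seed = 0
    cfg = PipelineConfig(seed=seed, **sections)
    problems.extend(cfg.problems())
    if problems:
        raise ConfigError(problems)
    return cfg


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file; an empty file resolves to all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(["config file must contain a YAML mapping"])
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Fully resolved config as plain data (for the run manifest)."""
    return dataclasses.asdict(cfg)
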
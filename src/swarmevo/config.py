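"""Configuration objects and TOML loading for the whole pipeline.

Defaults are the study conditions: a 900 x 9000 mm walled arena with the
nest (diameter 1000 mm) centred on one end wall and the food disk
(diameter 300 mm) near the opposite end, 30 robots of diameter 150 mm
moving at up to 100 mm/s, trials of 12,000 ticks of 0.1 s (20 simulated
minutes), and a Wright-Fisher population of N = 200 swarms with per-locus
mutation probability 0.001.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .genotype import ANCESTOR, FINAL, Genotype


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraint."""


@dataclass(frozen=True)
class ArenaConfig:
    field_width_mm: float = 900.0
    field_length_mm: float = 9000.0
    food_diameter_mm: float = 300.0
    nest_diameter_mm: float = 1000.0
    food_light_radius_mm: float = 600.0
    robot_diameter_mm: float = 150.0
    robot_max_speed_mm_s: float = 100.0
    n_robots: int = 30
    n_steps: int = 12000
    dt_s: float = 0.1

    # Derived geometry: nest centred on the y=0 end wall, food disk one
    # diameter in from the far wall, both on the arena mid-line.
    @property
    def nest_center(self) -> tuple[float, float]:
        return (self.field_width_mm / 2.0, 0.0)

    @property
    def food_center(self) -> tuple[float, float]:
        return (self.field_width_mm / 2.0, self.field_length_mm - self.food_diameter_mm)

    def validate(self) -> None:
        positive = (
            "field_width_mm", "field_length_mm", "food_diameter_mm", "nest_diameter_mm",
            "food_light_radius_mm", "robot_diameter_mm", "robot_max_speed_mm_s", "dt_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"arena.{name} must be > 0, got {getattr(self, name)}")
        if self.n_robots < 1:
            raise ConfigError(f"arena.n_robots must be >= 1, got {self.n_robots}")
        if self.n_steps < 0:
            raise ConfigError(f"arena.n_steps must be >= 0, got {self.n_steps}")
        if self.robot_diameter_mm >= self.field_width_mm:
            raise ConfigError("arena.robot_diameter_mm must be smaller than field_width_mm")
        # food and nest sit on opposite ends and must not overlap
        gap = (self.food_center[1] - self.nest_center[1])
        if gap <= (self.food_diameter_mm + self.nest_diameter_mm) / 2.0:
            raise ConfigError("arena: food and nest disks overlap; lengthen the field")
        if self.food_center[1] + self.food_diameter_mm / 2.0 > self.field_length_mm:
            raise ConfigError("arena: food disk does not fit inside the field")


@dataclass(frozen=True)
class PheromoneConfig:
    grid_cell_mm: float = 30.0
    deposit_amount_per_step: float = 3.0
    evaporation_coeff: float = 0.005
    diffusion_coeff: float = 0.02
    detection_threshold: float = 2.0

    def validate(self) -> None:
        if self.grid_cell_mm <= 0:
            raise ConfigError(f"pheromone.grid_cell_mm must be > 0, got {self.grid_cell_mm}")
        if not 0.0 < self.evaporation_coeff <= 1.0:
            raise ConfigError(
                f"pheromone.evaporation_coeff must be in (0, 1], got {self.evaporation_coeff}")
        if not 0.0 <= self.diffusion_coeff <= 0.25:
            # explicit 4-neighbour scheme is mass-conserving and stable only up to 1/4
            raise ConfigError(
                f"pheromone.diffusion_coeff must be in [0, 0.25], got {self.diffusion_coeff}")
        if self.deposit_amount_per_step < 0:
            raise ConfigError("pheromone.deposit_amount_per_step must be >= 0")
        if self.detection_threshold <= 0:
            raise ConfigError("pheromone.detection_threshold must be > 0")


@dataclass(frozen=True)
class BehaviorConfig:
    stay_duration_s: float = 0.9
    leave_distance_mm: float = 150.0
    heading_sigma_rad: float = 0.2
    motor_noise_rad: float = 0.05
    sensor_angle_rad: float = 0.5
    sensor_offset_mm: float = 90.0
    s3_turn_rad: float = 0.3
    s3_outbound_cone_rad: float = 1.0471975511965976  # 60 degrees
    trail_lost_steps: int = 40

    def validate(self) -> None:
        for name in ("stay_duration_s", "leave_distance_mm", "heading_sigma_rad",
                     "motor_noise_rad", "sensor_angle_rad", "sensor_offset_mm", "s3_turn_rad",
                     "s3_outbound_cone_rad"):
            if getattr(self, name) < 0:
                raise ConfigError(f"behavior.{name} must be >= 0, got {getattr(self, name)}")
        if self.trail_lost_steps < 1:
            raise ConfigError("behavior.trail_lost_steps must be >= 1")


@dataclass(frozen=True)
class EvolutionConfig:
    n_swarms: int = 200
    mutation_rate: float = 0.001
    initial_genotype: Genotype = ANCESTOR
    target_genotype: Genotype = FINAL
    max_generations: int = 10000

    def validate(self) -> None:
        if self.n_swarms < 2:
            raise ConfigError(f"evolution.n_swarms must be >= 2, got {self.n_swarms}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError(
                f"evolution.mutation_rate must be in [0, 1], got {self.mutation_rate}")
        if self.max_generations < 1:
            raise ConfigError("evolution.max_generations must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Bundle of all configuration tables."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    pheromone: PheromoneConfig = field(default_factory=PheromoneConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)

    def validate(self) -> "SimConfig":
        self.arena.validate()
        self.pheromone.validate()
        self.behavior.validate()
        self.evolution.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["evolution"]["initial_genotype"] = str(self.evolution.initial_genotype)
        d["evolution"]["target_genotype"] = str(self.evolution.target_genotype)
        return d


def reduced_config(field_length_mm: float = 3000.0, n_steps: int = 3000,
                   food_light_radius_mm: float = 300.0) -> SimConfig:
    """Desk-scale study conditions: a one-third-length arena, 5 simulated
    minutes, and a food light scaled with the arena so the search problem
    keeps its difficulty relative to trail recruitment.

    Everything else (robot count, kinematics, pheromone dynamics, population
    parameters) is kept at the full-scale defaults.
    """
    return SimConfig(
        arena=dataclasses.replace(ArenaConfig(), field_length_mm=field_length_mm,
                                  n_steps=n_steps,
                                  food_light_radius_mm=food_light_radius_mm)
    ).validate()


_TABLES = {
    "arena": ArenaConfig,
    "pheromone": PheromoneConfig,
    "behavior": BehaviorConfig,
    "evolution": EvolutionConfig,
}


def resolve_config(data: dict) -> SimConfig:
    """Build a validated :class:`SimConfig` from a (possibly partial) dict.

    Unknown tables or keys raise :class:`ConfigError` naming the key; missing
    keys take the documented defaults.
    """
    sections: dict[str, object] = {}
    for table, payload in data.items():
        cls = _TABLES.get(table)
        if cls is None:
            raise ConfigError(f"unknown config table: [{table}]")
        if not isinstance(payload, dict):
            raise ConfigError(f"config table [{table}] must be a table of key = value pairs")
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in payload.items():
            if key not in fields:
                raise ConfigError(f"unknown config key: {table}.{key}")
            if key in ("initial_genotype", "target_genotype") and isinstance(value, str):
                value = Genotype.from_string(value)
            kwargs[key] = value
        try:
            sections[table] = cls(**kwargs)
        except TypeError as exc:  # wrong value type
            raise ConfigError(f"bad value in [{table}]: {exc}") from exc
    return SimConfig(**sections).validate()


def load_config(path: str | Path | None) -> SimConfig:
    """Load a TOML config file; ``None`` or an empty file yields the defaults."""
    if path is None:
        return SimConfig().validate()
    p = Path(path)
    with open(p, "rb") as fh:
        data = tomllib.load(fh)
    return resolve_config(data)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dumps_toml(config: SimConfig) -> str:
    """Serialize the fully resolved config back to TOML (round-trips)."""
    out = []
    for table, payload in config.to_dict().items():
        out.append(f"[{table}]")
        for key, value in payload.items():
            out.append(f"{key} = {_toml_scalar(value)}")
        out.append("")
    return "\n".join(out)
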
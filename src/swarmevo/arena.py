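"""Embodied agent-based simulation of one swarm foraging trial.

A trial puts ``n_robots`` disk-shaped robots into a walled rectangular
arena with a food disk at one end and the nest beacon at the other.  Each
robot runs the three-state controller

* ``S1`` searching: correlated random walk, phototaxis toward the food
  light when within range;
* ``S2`` carrying/recruiting: homes in on the nest beacon at full speed
  while depositing trail pheromone every tick;
* ``S3`` recruited: follows the pheromone trail outbound with two forward
  concentration sensors (reachable only when the genotype can detect the
  pheromone, p = 1).

On robot-robot contact each body reacts according to the allele at the
locus matching its current state: Stay (freeze for a fixed time) or Leave
(back up a fixed distance).  The swarm's fitness is the number of completed
food deliveries (foraging bouts) in the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernel
from .config import ArenaConfig, BehaviorConfig, ConfigError, PheromoneConfig, SimConfig
from .genotype import Genotype

S1, S2, S3 = 1, 2, 3
STAY, LEAVE = "stay", "leave"


@dataclass
class Percepts:
    """Local sensing snapshot used by the state machine."""

    food_light_visible: bool = False
    at_food: bool = False
    at_nest: bool = False
    pheromone: float = 0.0
    trail_lost_count: int = 0


@dataclass
class RobotState:
    position: np.ndarray  # (2,) mm
    heading: float  # radians
    behavior_state: int = S1
    stay_timer: int = 0
    leave_distance_remaining: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.stay_timer > 0 and self.leave_distance_remaining > 0:
            raise ValueError("stay_timer and leave_distance_remaining cannot both be active")


@dataclass
class TrialResult:
    """Per-trial summary: bouts are the swarm's fitness."""

    genotype: Genotype
    seed: int
    bouts: int
    collisions: int
    state_steps: tuple[int, int, int]  # ticks spent in S1/S2/S3, summed over robots
    n_steps: int
    event_log: Optional[list] = None

    def as_row(self) -> dict:
        return {
            "genotype": str(self.genotype),
            "seed": self.seed,
            "bouts": self.bouts,
            "collisions": self.collisions,
            "s1_steps": self.state_steps[0],
            "s2_steps": self.state_steps[1],
            "s3_steps": self.state_steps[2],
            "n_steps": self.n_steps,
        }


@dataclass
class WorldState:
    """Mutable simulation state advanced tick by tick."""

    positions: np.ndarray  # (n, 2)
    headings: np.ndarray  # (n,)
    states: np.ndarray  # (n,) in {1,2,3}
    stay_timers: np.ndarray  # (n,) int
    leave_remaining: np.ndarray  # (n,) float
    lost_counts: np.ndarray  # (n,) int
    contacts: np.ndarray  # (n, n) uint8 pair-contact memory
    pheromone_field: np.ndarray  # (ny, nx)
    step_index: int = 0
    bouts: int = 0
    collisions: int = 0
    state_steps: np.ndarray = dc_field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    pher_active: bool = False
    _noise_gens: Optional[list] = None
    _buf: Optional[np.ndarray] = None

    @property
    def n_robots(self) -> int:
        return self.positions.shape[0]

    def robot(self, i: int) -> RobotState:
        return RobotState(
            position=self.positions[i].copy(),
            heading=float(self.headings[i]),
            behavior_state=int(self.states[i]),
            stay_timer=int(self.stay_timers[i]),
            leave_distance_remaining=float(self.leave_remaining[i]),
        )


def _noise_generators(seed: int, n_robots: int) -> list:
    """Independent, prefix-stable per-robot noise streams."""
    return [
        np.random.Generator(np.random.Philox(np.random.SeedSequence(entropy=int(seed),
                                                                    spawn_key=(1, i))))
        for i in range(n_robots)
    ]


def initial_world(config: SimConfig, seed: int) -> WorldState:
    """Seeded random initial placement (non-overlapping bodies) in state S1."""
    arena = config.arena
    pm = _kernel.make_params(arena, config.pheromone, config.behavior)
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,))))
    n = arena.n_robots
    r = arena.robot_diameter_mm / 2.0
    pos = np.empty((n, 2))
    placed = 0
    tries = 0
    while placed < n:
        tries += 1
        if tries > 100000:
            raise ConfigError("could not place robots without overlap; arena too crowded")
        x = rng.uniform(r, arena.field_width_mm - r)
        y = rng.uniform(r, arena.field_length_mm - r)
        ok = True
        for k in range(placed):
            if (pos[k, 0] - x) ** 2 + (pos[k, 1] - y) ** 2 < (2 * r) ** 2:
                ok = False
                break
        if ok:
            pos[placed, 0] = x
            pos[placed, 1] = y
            placed += 1
    headings = rng.uniform(-math.pi, math.pi, size=n)
    world = WorldState(
        positions=pos,
        headings=headings,
        states=np.full(n, S1, dtype=np.int64),
        stay_timers=np.zeros(n, dtype=np.int64),
        leave_remaining=np.zeros(n, dtype=np.float64),
        lost_counts=np.zeros(n, dtype=np.int64),
        contacts=np.zeros((n, n), dtype=np.uint8),
        pheromone_field=np.zeros((pm.ny, pm.nx), dtype=np.float64),
    )
    world._noise_gens = _noise_generators(seed, n)
    world._buf = np.zeros((pm.ny, pm.nx), dtype=np.float64)
    return world


def transition_state(robot: RobotState, percepts: Percepts, genotype: Genotype,
                     detection_threshold: float = PheromoneConfig().detection_threshold,
                     trail_lost_steps: int = BehaviorConfig().trail_lost_steps) -> RobotState:
    """Apply one state-machine transition; deterministic given the percepts.

    ``S3`` is reachable only when the genotype carries p = 1: the detection
    flag handed to the state machine is the conjunction of the allele and
    the local concentration reading.
    """
    if robot.behavior_state not in (S1, S2, S3):
        raise ValueError(f"unknown behavior_state: {robot.behavior_state}")
    detect = genotype.p == 1 and percepts.pheromone >= detection_threshold
    new_state, bout = _kernel.transition_code(
        robot.behavior_state, percepts.at_food, percepts.at_nest, detect,
        percepts.trail_lost_count, trail_lost_steps)
    out = RobotState(robot.position.copy(), robot.heading, int(new_state),
                     robot.stay_timer, robot.leave_distance_remaining)
    out.bout = bool(bout)  # annotation for callers that count deliveries
    return out


def resolve_collision(robot_a: RobotState, robot_b: RobotState, genotype: Genotype,
                      robot_diameter_mm: float = ArenaConfig().robot_diameter_mm
                      ) -> tuple[str, str]:
    """Collision reactions of two touching clone-mates.

    Each robot reads the allele at the locus matching its *own* current
    state: 0 -> Stay, 1 -> Leave.  Non-contacting bodies are a contract
    violation.
    """
    d = float(np.hypot(*(robot_a.position - robot_b.position)))
    if d > robot_diameter_mm + 1e-9:
        raise ValueError(
            f"resolve_collision called on non-contacting robots (distance {d:.1f} mm)")
    reactions = []
    for robot in (robot_a, robot_b):
        allele = genotype.collision_allele(robot.behavior_state)
        reactions.append(STAY if allele == 0 else LEAVE)
    return reactions[0], reactions[1]


def update_pheromone(field: np.ndarray, deposits: list[tuple[tuple[float, float], float]],
                     config: PheromoneConfig, arena: ArenaConfig | None = None) -> np.ndarray:
    """Add deposits, then one tick of diffusion and evaporation.

    ``deposits`` is a list of ((x_mm, y_mm), amount).  A deposit outside the
    field raises an error naming the offending position.
    """
    arena = arena or ArenaConfig()
    out = np.array(field, dtype=np.float64, copy=True)
    ny, nx = out.shape
    for (x, y), amount in deposits:
        if not (0.0 <= x <= arena.field_width_mm and 0.0 <= y <= arena.field_length_mm):
            raise ValueError(f"deposit outside field at position ({x}, {y}) mm")
        iy, ix = _kernel.cell_index(float(x), float(y), config.grid_cell_mm, ny, nx)
        out[iy, ix] += float(amount)
    buf = np.empty_like(out)
    _kernel.diffuse_evaporate(out, buf, config.diffusion_coeff, config.evaporation_coeff)
    return out


def step_world(world: WorldState, genotype: Genotype, config: SimConfig) -> WorldState:
    """Advance the world by one synchronous tick (in place)."""
    pm = _kernel.make_params(config.arena, config.pheromone, config.behavior)
    if world._noise_gens is None:
        raise ValueError("world has no noise streams; build it with initial_world()")
    if world._buf is None:
        world._buf = np.zeros_like(world.pheromone_field)
    noise = np.array([g.standard_normal() for g in world._noise_gens])
    b, c, c1, c2, c3, active = _kernel.step(
        world.positions, world.headings, world.states, world.stay_timers,
        world.leave_remaining, world.lost_counts, world.contacts,
        world.pheromone_field, world._buf, noise, genotype.as_array(), pm,
        world.pher_active)
    world.pher_active = bool(active)
    world.bouts += int(b)
    world.collisions += int(c)
    world.state_steps += np.array([c1, c2, c3], dtype=np.int64)
    world.step_index += 1
    return world


def simulate_trial(genotype: Genotype, config: SimConfig, seed: int,
                   n_steps: int | None = None) -> TrialResult:
    """Run one seeded foraging trial; bit-identical for identical inputs.

    Per-robot noise comes from counter-based streams derived from the trial
    seed, so a longer trial replays the same prefix (bout counts are
    non-decreasing in ``n_steps`` under the same seed).
    """
    config.validate()
    steps = config.arena.n_steps if n_steps is None else int(n_steps)
    if steps < 0:
        raise ConfigError(f"n_steps must be >= 0, got {steps}")
    world = initial_world(config, seed)
    if steps == 0:
        return TrialResult(genotype, int(seed), 0, 0, (0, 0, 0), 0)
    pm = _kernel.make_params(config.arena, config.pheromone, config.behavior)
    n = config.arena.n_robots
    noise = np.empty((steps, n))
    for i, g in enumerate(world._noise_gens):
        noise[:, i] = g.standard_normal(steps)
    budgets = np.zeros(3, dtype=np.int64)
    bouts, colls = _kernel.run_trial(
        world.positions, world.headings, world.states, world.stay_timers,
        world.leave_remaining, world.lost_counts, world.contacts,
        world.pheromone_field, world._buf, noise, genotype.as_array(), pm,
        steps, budgets)
    return TrialResult(genotype, int(seed), int(bouts), int(colls),
                       (int(budgets[0]), int(budgets[1]), int(budgets[2])), steps)
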
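"""Wright-Fisher evolution of a population of clonal swarms.

Each of N swarms carries one 4-locus genome.  Every generation each swarm
realizes a single noisy fitness value (one foraging trial, or one draw from
stored per-genotype fitness samples), parents are sampled in proportion to
realized fitness with replacement, and each offspring genome mutates at
each locus independently with probability mu.  Runs start from an
all-``{0,0,0;0}`` population and stop when the target genotype
``{1,0,1;1}`` is fixed.  The full parent map is kept so the genealogy of
the fixed genotype can be traced and the order of its b3 and p mutations
classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Protocol

import numpy as np

from .config import EvolutionConfig, SimConfig
from .genotype import ORIGINAL, Genotype

logger = logging.getLogger(__name__)

LOCUS_NAMES = ("b1", "b2", "b3", "p")
_B3, _P = 2, 3  # locus columns


class FitnessProvider(Protocol):
    """Realizes one fitness value per swarm per generation."""

    def draw(self, genotype_indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        ...


class SurrogateFitness:
    """Sample stored per-genotype fitness distributions (fast path)."""

    def __init__(self, samples: dict[Genotype, np.ndarray] | dict[int, np.ndarray]):
        self._samples: dict[int, np.ndarray] = {}
        for key, arr in samples.items():
            idx = key.index if isinstance(key, Genotype) else int(key)
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                raise ValueError(f"empty fitness sample vector for genotype index {idx}")
            self._samples[idx] = arr

    @classmethod
    def from_distributions(cls, landscape) -> "SurrogateFitness":
        return cls({g: d.samples for g, d in landscape.items()})

    def draw(self, genotype_indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(len(genotype_indices), dtype=np.float64)
        for idx in np.unique(genotype_indices):
            arr = self._samples.get(int(idx))
            if arr is None:
                raise KeyError(f"no fitness samples for genotype {Genotype.from_index(int(idx))}")
            sel = genotype_indices == idx
            out[sel] = arr[rng.integers(0, len(arr), size=int(sel.sum()))]
        return out


class LiveFitness:
    """Run one embodied foraging trial per swarm per generation (slow path)."""

    def __init__(self, config: SimConfig):
        self.config = config

    def draw(self, genotype_indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        from .arena import simulate_trial
        out = np.empty(len(genotype_indices), dtype=np.float64)
        for i, idx in enumerate(genotype_indices):
            seed = int(rng.integers(0, 2**31))
            out[i] = simulate_trial(Genotype.from_index(int(idx)), self.config, seed).bouts
        return out


@dataclass
class MutationEvent:
    generation: int
    swarm: int
    locus: str
    frm: int
    to: int


@dataclass
class Population:
    generation: int
    genotypes: np.ndarray  # (N, 4) uint8 allele matrix
    fitness: np.ndarray  # (N,) realized fitness this generation

    @property
    def indices(self) -> np.ndarray:
        g = self.genotypes
        return (g[:, 0] * 8 + g[:, 1] * 4 + g[:, 2] * 2 + g[:, 3]).astype(np.uint8)


@dataclass
class EvolutionRun:
    config: EvolutionConfig
    genotype_history: list  # per generation: (N,) uint8 genotype indices
    parent_history: list  # per generation g>=1: (N,) parent index in g-1
    mutation_events: list
    fixation_generation: Optional[int]
    fixed: bool
    uniform_fallbacks: int = 0  # generations where all fitness was zero

    @property
    def n_generations(self) -> int:
        return len(self.genotype_history) - 1

    def frequency_table(self) -> np.ndarray:
        """(generations+1, 16) genotype frequencies; rows sum to 1."""
        N = self.config.n_swarms
        out = np.zeros((len(self.genotype_history), 16))
        for g, idx in enumerate(self.genotype_history):
            out[g] = np.bincount(idx, minlength=16) / N
        return out

    def focal_lineage(self) -> tuple[np.ndarray, np.ndarray]:
        """Trace the lowest-index swarm of the fixed generation back to
        generation 0.  Returns (swarm index per generation, genotype index
        per generation)."""
        if not self.fixed:
            raise ValueError("run did not reach fixation; no focal genealogy")
        G = self.fixation_generation
        swarms = np.empty(G + 1, dtype=np.int64)
        swarms[G] = 0
        for g in range(G, 0, -1):
            swarms[g - 1] = self.parent_history[g - 1][swarms[g]]
        genos = np.array([self.genotype_history[g][swarms[g]] for g in range(G + 1)],
                         dtype=np.int64)
        return swarms, genos


@dataclass
class PathClass:
    label: str  # b3_first | p_first | irregular
    events: list = field(default_factory=list)  # (generation, locus, frm, to) on the lineage


def mutate_genotype(genotype: Genotype, mu: float, rng: np.random.Generator) -> Genotype:
    """Flip each of the four loci independently with probability mu."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mutation probability must be in [0, 1], got {mu}")
    bits = genotype.as_array()
    flips = rng.random(4) < mu
    return Genotype.from_bits(bits ^ flips)


def next_generation(pop: Population, config: EvolutionConfig, provider: FitnessProvider,
                    rng: np.random.Generator,
                    ) -> tuple[Population, np.ndarray, list, bool]:
    """One Wright-Fisher step.

    Returns (new population, parent map, mutation events, uniform_fallback).
    Parent sampling is fitness-proportional via inverse-CDF with one uniform
    draw per offspring; an all-zero-fitness generation falls back to uniform
    parent choice (logged), since proportionality is then undefined.
    """
    N = config.n_swarms
    fit = pop.fitness
    if (fit < 0).any():
        raise ValueError("realized fitness must be non-negative")
    total = float(fit.sum())
    fallback = total == 0.0
    if fallback:
        logger.warning("generation %d: all realized fitness zero; uniform parent choice",
                       pop.generation)
        parents = rng.integers(0, N, size=N)
    else:
        cum = np.cumsum(fit)
        parents = np.searchsorted(cum, rng.random(N) * total, side="right")
        parents = np.minimum(parents, N - 1)
    offspring = pop.genotypes[parents].copy()
    flips = rng.random((N, 4)) < config.mutation_rate
    offspring ^= flips.astype(np.uint8)
    gen = pop.generation + 1
    events = [
        MutationEvent(gen, int(s), LOCUS_NAMES[l],
                      int(offspring[s, l] ^ 1), int(offspring[s, l]))
        for s, l in np.argwhere(flips)
    ]
    fitness = provider.draw(
        (offspring[:, 0] * 8 + offspring[:, 1] * 4 + offspring[:, 2] * 2
         + offspring[:, 3]).astype(np.int64), rng)
    return Population(gen, offspring, fitness), parents, events, fallback


def run_evolution(config: EvolutionConfig, provider: FitnessProvider, seed: int,
                  ) -> EvolutionRun:
    """Iterate Wright-Fisher generations until the target genotype fixes.

    The max-generation guard returns a partial run flagged unfixed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xE7071)))
    N = config.n_swarms
    init = np.tile(config.initial_genotype.as_array().astype(np.uint8), (N, 1))
    pop = Population(0, init, provider.draw(
        np.full(N, config.initial_genotype.index, dtype=np.int64), rng))
    target = config.target_genotype.index
    genotype_history = [pop.indices]
    parent_history: list[np.ndarray] = []
    events: list[MutationEvent] = []
    fallbacks = 0
    fixation = None
    for _ in range(config.max_generations):
        pop, parents, ev, fb = next_generation(pop, config, provider, rng)
        genotype_history.append(pop.indices)
        parent_history.append(parents)
        events.extend(ev)
        fallbacks += int(fb)
        if (genotype_history[-1] == target).all():
            fixation = pop.generation
            break
    return EvolutionRun(config, genotype_history, parent_history, events,
                        fixation, fixation is not None, fallbacks)


def _lineage_flips(genos: np.ndarray) -> list[tuple[int, int, int, int]]:
    """(generation, locus, frm, to) for every allele change along a lineage
    of genotype indices."""
    out = []
    for g in range(1, len(genos)):
        diff = int(genos[g - 1]) ^ int(genos[g])
        for locus in range(4):
            bit = 1 << (3 - locus)
            if diff & bit:
                frm = (int(genos[g - 1]) >> (3 - locus)) & 1
                out.append((g, locus, frm, frm ^ 1))
    return out


_B3_FIRST_SET = {ORIGINAL.index, ORIGINAL.index | 2, ORIGINAL.index | 3}  # {1,0,0;0},{1,0,1;0},{1,0,1;1}
_P_FIRST_SET = {ORIGINAL.index, ORIGINAL.index | 1, ORIGINAL.index | 3}  # {1,0,0;0},{1,0,0;1},{1,0,1;1}


def classify_genealogy(run: EvolutionRun) -> PathClass:
    """Order of the 0->1 mutations at loci b3 and p along the focal lineage.

    ``b3_first``: after the lineage first carries {1,0,0;0}, the first 0->1
    flip at b3 strictly precedes the first 0->1 flip at p and the lineage
    visits only shortest-path genotypes thereafter; ``p_first`` is the
    mirror image; anything else (including lineages that never carry
    {1,0,0;0} or take detours) is ``irregular``.
    """
    if not run.fixed:
        raise ValueError("cannot classify an unfixed run")
    _, genos = run.focal_lineage()
    anchors = np.flatnonzero(genos == ORIGINAL.index)
    flips = _lineage_flips(genos)
    if len(anchors) == 0:
        return PathClass("irregular", flips)
    t0 = int(anchors[0])
    after = [f for f in flips if f[0] > t0]
    first_b3 = next((f[0] for f in after if f[1] == _B3 and f[2] == 0), None)
    first_p = next((f[0] for f in after if f[1] == _P and f[2] == 0), None)
    visited = set(int(g) for g in genos[t0:])
    if first_b3 is not None and (first_p is None or first_b3 < first_p):
        if visited <= _B3_FIRST_SET:
            return PathClass("b3_first", after)
    if first_p is not None and (first_b3 is None or first_p < first_b3):
        if visited <= _P_FIRST_SET:
            return PathClass("p_first", after)
    return PathClass("irregular", after)


def peak_frequency_before_tunneling(run: EvolutionRun) -> float:
    """Peak population frequency of {1,0,0;0} before the focal lineage's
    first 0->1 mutation at b3 or p.

    The cut-off is the first such mutation after the lineage first carries
    {1,0,0;0} (falling back to the first such mutation anywhere on the
    lineage if it never does).
    """
    if not run.fixed:
        raise ValueError("run did not reach fixation")
    _, genos = run.focal_lineage()
    flips = _lineage_flips(genos)
    anchors = np.flatnonzero(genos == ORIGINAL.index)
    t0 = int(anchors[0]) if len(anchors) else 0
    cut = next((f[0] for f in flips if f[0] > t0 and f[1] in (_B3, _P) and f[2] == 0), None)
    if cut is None:
        cut = next((f[0] for f in flips if f[1] in (_B3, _P) and f[2] == 0),
                   len(genos))
    freqs = run.frequency_table()[:cut, ORIGINAL.index]
    return float(freqs.max()) if len(freqs) else 0.0
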
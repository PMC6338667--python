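"""Fitness-landscape mapping over the 16 swarm genotypes.

Repeated independent foraging trials give an empirical distribution of
swarm fitness (bout counts) per genotype; bootstrap resampling of those
samples yields distributions of relative mean fitness against the
``{1,0,0;0}`` baseline (the quantities r0, r- and a consumed by the
evolutionary and tunneling layers).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import simulate_trial
from .config import SimConfig
from .genotype import ALL_GENOTYPES, ORIGINAL, Genotype


def config_fingerprint(config: SimConfig) -> str:
    """Stable digest tying fitness samples to the generating conditions."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def trial_seed(seed_base: int, trial_index: int) -> int:
    """Per-trial seed derived by counter; independent of the genotype so
    that genotypes neutral to each other receive identical trial streams."""
    ss = np.random.SeedSequence(entropy=(int(seed_base), int(trial_index)))
    return int(ss.generate_state(1, np.uint32)[0])


@dataclass
class FitnessDistribution:
    genotype: Genotype
    samples: np.ndarray  # per-trial bout counts
    collision_samples: np.ndarray  # per-trial collision counts
    n_trials: int
    config_fingerprint: str
    seed_base: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        self.collision_samples = np.asarray(self.collision_samples, dtype=np.int64)
        if len(self.samples) != self.n_trials:
            raise ValueError("samples length must equal n_trials")
        if (self.samples < 0).any():
            raise ValueError("fitness samples must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())


@dataclass
class RelativeFitnessSamples:
    genotype: Genotype
    baseline: Genotype
    ratios: np.ndarray  # bootstrap replicates of mean(genotype)/mean(baseline)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        if (self.ratios < 0).any():
            raise ValueError("relative fitness ratios must be >= 0")


def estimate_fitness_samples(genotype: Genotype, n_trials: int, config: SimConfig,
                             seed: int) -> FitnessDistribution:
    """Run ``n_trials`` independent trials and keep every sample."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    bouts = np.empty(n_trials, dtype=np.int64)
    colls = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        res = simulate_trial(genotype, config, trial_seed(seed, t))
        bouts[t] = res.bouts
        colls[t] = res.collisions
    return FitnessDistribution(genotype, bouts, colls, n_trials,
                               config_fingerprint(config), int(seed))


def map_landscape(config: SimConfig, n_trials: int, seed: int,
                  genotypes: tuple[Genotype, ...] = ALL_GENOTYPES,
                  ) -> dict[Genotype, FitnessDistribution]:
    """Fitness distributions for every requested genotype (default: all 16)."""
    return {g: estimate_fitness_samples(g, n_trials, config, seed) for g in genotypes}


def relative_fitness(dist: FitnessDistribution, baseline: FitnessDistribution,
                     n_boot: int = 10000, seed: int = 0) -> RelativeFitnessSamples:
    """Bootstrap distribution of the ratio of mean swarm fitness.

    Each replicate resamples both distributions with replacement and takes
    the ratio of resampled means; replicates with a zero baseline mean are
    undefined and raise.
    """
    if dist.config_fingerprint != baseline.config_fingerprint:
        raise ValueError("fitness distributions come from different configurations")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xB007)))
    n_d, n_b = len(dist.samples), len(baseline.samples)
    num = dist.samples[rng.integers(0, n_d, size=(n_boot, n_d))].mean(axis=1)
    den = baseline.samples[rng.integers(0, n_b, size=(n_boot, n_b))].mean(axis=1)
    if (den == 0).any():
        raise ValueError("baseline bootstrap mean of zero: relative fitness undefined")
    return RelativeFitnessSamples(dist.genotype, baseline.genotype, num / den)


def valley_relative_fitness(landscape: dict[Genotype, FitnessDistribution],
                            n_boot: int = 10000, seed: int = 0,
                            ) -> dict[str, RelativeFitnessSamples]:
    """The three relative-fitness distributions of the valley-crossing story:
    r0 (neutral intermediate), r_minus (inferior intermediate) and a (final),
    each against the original genotype {1,0,0;0}."""
    from .genotype import FINAL, INFERIOR_INTERMEDIATE, NEUTRAL_INTERMEDIATE
    base = landscape[ORIGINAL]
    return {
        "r0": relative_fitness(landscape[NEUTRAL_INTERMEDIATE], base, n_boot, seed),
        "r_minus": relative_fitness(landscape[INFERIOR_INTERMEDIATE], base, n_boot, seed + 1),
        "a": relative_fitness(landscape[FINAL], base, n_boot, seed + 2),
    }


def landscape_frame(landscape: dict[Genotype, FitnessDistribution]) -> pd.DataFrame:
    """One row per trial (long format) for CSV export."""
    rows = []
    for g, dist in landscape.items():
        for t, (b, c) in enumerate(zip(dist.samples, dist.collision_samples)):
            rows.append({"genotype": str(g), "trial": t, "bouts": int(b),
                         "collisions": int(c)})
    return pd.DataFrame(rows)


def summary_frame(landscape: dict[Genotype, FitnessDistribution]) -> pd.DataFrame:
    rows = []
    for g, dist in landscape.items():
        rows.append({
            "genotype": str(g),
            "n": dist.n_trials,
            "mean_bouts": float(dist.samples.mean()),
            "var_bouts": float(dist.samples.var(ddof=1)) if dist.n_trials > 1 else 0.0,
            "mean_collisions": float(dist.collision_samples.mean()),
        })
    return pd.DataFrame(rows)


def save_landscape(landscape: dict[Genotype, FitnessDistribution], path: str | Path) -> None:
    landscape_frame(landscape).to_csv(path, index=False)


def load_landscape_samples(path: str | Path) -> dict[Genotype, np.ndarray]:
    """Read per-trial bout samples back from a landscape CSV."""
    df = pd.read_csv(path)
    out: dict[Genotype, np.ndarray] = {}
    for name, grp in df.groupby("genotype"):
        out[Genotype.from_string(str(name))] = grp.sort_values("trial")["bouts"].to_numpy()
    return out
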
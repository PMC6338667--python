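"""Run orchestration, seed management and result serialization.

A pipeline stage executes with seeds derived deterministically from one
master seed, writes CSV/JSON payloads with fixed numeric formatting, and
records a manifest (resolved config, seed, command, file checksums) so a
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import SimConfig
from .evolution import SurrogateFitness, classify_genealogy, peak_frequency_before_tunneling, run_evolution
from .fitness import map_landscape, save_landscape, summary_frame, valley_relative_fitness
from .genotype import ORIGINAL
from .tunneling import predict_outcome_sets

logger = logging.getLogger(__name__)

STAGES = ("landscape", "evolve", "tunnel", "full")

# fixed stage offsets so adding trials or stages never perturbs other seeds
_STAGE_KEY = {"landscape": 1, "evolve": 2, "tunnel": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=(int(master_seed), _STAGE_KEY[stage]))
    return int(ss.generate_state(1, np.uint32)[0])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    seed: int
    stage: str
    config: dict
    version: str = __version__
    command: str = ""
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    log: list = field(default_factory=list)
    error: str | None = None

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(stage: str, config: SimConfig, seed: int, out_dir: str | Path,
                 n_trials: int = 200, replicates: int = 50, n_boot: int = 10000,
                 n_sets: int = 1000, set_size: int = 50) -> RunManifest:
    """Execute one stage (or the full chain) and write a manifest.

    ``full`` chains landscape -> evolve (surrogate fitness from the fresh
    landscape) -> tunnel (relative-fitness bootstraps from the same
    landscape).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=int(seed), stage=stage, config=config.to_dict(),
                           command=" ".join(sys.argv),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    produced: list[Path] = []
    try:
        landscape = None
        if stage in ("landscape", "full"):
            landscape = map_landscape(config, n_trials, stage_seed(seed, "landscape"))
            p = out / "landscape_trials.csv"
            save_landscape(landscape, p)
            produced.append(p)
            p = out / "landscape_summary.csv"
            summary_frame(landscape).to_csv(p, index=False, float_format="%.6f")
            produced.append(p)
        if stage in ("evolve", "full"):
            if landscape is None:
                landscape = map_landscape(config, n_trials, stage_seed(seed, "landscape"))
            provider = SurrogateFitness.from_distributions(landscape)
            runs = []
            base = stage_seed(seed, "evolve")
            for rep in range(replicates):
                run = run_evolution(config.evolution, provider, base + rep)
                entry = {"replicate": rep, "fixed": run.fixed,
                         "fixation_generation": run.fixation_generation,
                         "uniform_fallbacks": run.uniform_fallbacks}
                if run.fixed:
                    entry["path_class"] = classify_genealogy(run).label
                    entry["peak_original_frequency"] = round(
                        peak_frequency_before_tunneling(run), 6)
                runs.append(entry)
                if run.uniform_fallbacks:
                    manifest.log.append(
                        f"evolve replicate {rep}: {run.uniform_fallbacks} uniform fallbacks")
            p = out / "evolution_runs.json"
            _json_dump({"replicates": runs}, p)
            produced.append(p)
        if stage in ("tunnel", "full"):
            if landscape is None:
                landscape = map_landscape(config, n_trials, stage_seed(seed, "landscape"))
            rel = valley_relative_fitness(landscape, n_boot=n_boot,
                                          seed=stage_seed(seed, "tunnel"))
            pred = predict_outcome_sets(
                rel["r0"], rel["r_minus"], rel["a"], n_sets, set_size,
                N=config.evolution.n_swarms, mu=config.evolution.mutation_rate,
                seed=stage_seed(seed, "tunnel"))
            if pred.n_redrawn:
                manifest.log.append(f"tunnel: {pred.n_redrawn} non-positive draws redrawn")
            if pred.n_ties:
                manifest.log.append(f"tunnel: {pred.n_ties} exact ties -> neutral path")
            p = out / "tunneling_prediction.json"
            _json_dump({
                "n_sets": pred.n_sets,
                "set_size": pred.set_size,
                "neutral_count_percentiles": list(pred.count_percentiles),
                "mean_time_percentiles": list(pred.time_percentiles),
                "neutral_count_mean": float(np.mean(pred.neutral_counts)),
                "mean_time_mean": float(np.mean(pred.mean_times)),
                "baseline_genotype": str(ORIGINAL),
            }, p)
            produced.append(p)
    except Exception as exc:  # record the failure in the partial manifest
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.outputs = {p.name: _sha256(p) for p in produced}
        manifest.write(out)
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.outputs = {p.name: _sha256(p) for p in produced}
    manifest.write(out)
    return manifest
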
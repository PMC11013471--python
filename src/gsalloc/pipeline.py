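"""End-to-end pipeline: config, seeding substreams, artifact writing.

One global seed is expanded into named substreams (simulation, folds,
random-marker draws, model-based selection, core optimizer) so changing one
stage's draws never shifts another's.  Every stage writes its artifact to
the output directory and a JSON manifest captures config, seeds, and stage
timings; a rerun with the same config reproduces all outputs bit-for-bit
(timings aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as gio
from .cores import ibs_distance, select_core
from .io import FilterConfig, GenotypeMatrix, PhenotypeVector
from .markers import SelectionSchedule, schedule_sizes, restrict_schedule
from .pruning import PruneConfig, prune
from .simulate import SimConfig, simulate_population
from .validation import (
    CVConfig,
    results_frame,
    run_grid,
    run_strategy_comparison,
    run_ts_size_sweep,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "seed_substreams"]

_SUBSTREAMS = ("simulation", "folds", "nre_r", "re_mob", "core", "sweep", "grid")


def seed_substreams(seed: int) -> dict[str, int]:
    """Derive one named integer seed per pipeline stage from the global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_SUBSTREAMS, children)
    }


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    Exactly one of (``genotype_path``, ``sim``) must be set: real data in, or
    a simulated population.
    """

    genotype_path: Optional[str] = None
    genotype_map_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    validation_genotype_path: Optional[str] = None
    validation_phenotype_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    external_fraction: float = 0.15  # held out of a simulated population
    filter: FilterConfig = field(default_factory=FilterConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    retention_fraction: float = 0.30
    min_subset_size: int = 48
    strategies: tuple = ("NRE_MB", "NRE_R", "RE_MAB", "RE_MOB")
    core_fractions: tuple = (0.75, 0.5, 0.2, 0.1, 0.05)
    cv: CVConfig = field(default_factory=CVConfig)
    n_random_marker_reps: int = 100
    re_mob_reps: int = 100
    n_random_core_reps: int = 20
    core_restarts: int = 5
    run_sweep: bool = True
    run_grid_stage: bool = False
    seed: int = 0
    label: str = "run"

    def __post_init__(self) -> None:
        has_paths = self.genotype_path is not None
        has_sim = self.sim is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of genotype_path / sim must be given")
        if has_paths and self.phenotype_path is None:
            raise ValueError("genotype_path requires phenotype_path")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (nested sections filter/prune/cv/sim)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "sim" in kwargs and kwargs["sim"] is not None:
        kwargs["sim"] = SimConfig(**kwargs["sim"])
    for key, cls in (("filter", FilterConfig), ("prune", PruneConfig), ("cv", CVConfig)):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = cls(**kwargs[key])
    for key in ("strategies", "core_fractions"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, seeds: dict):
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=seeds["simulation"])
        G, y, truth = simulate_population(sim)
        rng = np.random.default_rng(seeds["simulation"] + 1)
        n_ext = max(3, int(round(cfg.external_fraction * G.n_genotypes)))
        ext = np.sort(rng.choice(G.n_genotypes, size=n_ext, replace=False))
        mask = np.zeros(G.n_genotypes, dtype=bool)
        mask[ext] = True
        ids = np.array(G.genotype_ids)
        G_tr = G.subset_genotypes(list(ids[~mask]))
        G_ev = G.subset_genotypes(list(ids[mask]))
        y_tr = y.subset(list(ids[~mask]))
        y_ev = y.subset(list(ids[mask]))
        return G_tr, y_tr, G_ev, y_ev, truth
    if str(cfg.genotype_path).endswith((".vcf", ".vcf.gz")):
        G = gio.read_genotypes_vcf(cfg.genotype_path)
    else:
        G = gio.read_genotypes_table(cfg.genotype_path, cfg.genotype_map_path)
    y = gio.read_phenotypes(cfg.phenotype_path)
    G_ev = y_ev = None
    if cfg.validation_genotype_path:
        if str(cfg.validation_genotype_path).endswith((".vcf", ".vcf.gz")):
            G_ev = gio.read_genotypes_vcf(cfg.validation_genotype_path)
        else:
            G_ev = gio.read_genotypes_table(cfg.validation_genotype_path)
        y_ev = gio.read_phenotypes(cfg.validation_phenotype_path)
    return G, y, G_ev, y_ev, None


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute filter -> impute -> prune -> marker strategies -> core sweep
    (-> grid), writing artifacts and a manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = seed_substreams(cfg.seed)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "substream_seeds": seeds,
        "stages": {},
    }
    t0 = time.time()

    def stage_done(name):
        manifest["stages"][name] = round(time.time() - t0, 3)

    G, y, G_ev, y_ev, truth = _load_inputs(cfg, seeds)
    if truth is not None:
        truth.to_json(outdir / "truth.json")
    stage_done("load")

    G = gio.filter_markers(G, cfg.filter)
    if G.n_markers == 0:
        raise RuntimeError("stage filter: no markers survived QC")
    G = gio.impute_mean(G)
    stage_done("filter_impute")

    Gp = prune(G, cfg.prune)
    (outdir / "pruned_markers.txt").write_text("\n".join(Gp.marker_ids) + "\n")
    stage_done("prune")
    if G_ev is not None:
        G_ev = gio.impute_mean(G_ev)

    schedule = schedule_sizes(Gp.n_markers, cfg.retention_fraction, cfg.min_subset_size)
    schedule = restrict_schedule(schedule, Gp.n_markers)
    results = run_strategy_comparison(
        Gp, y, G_ev, y_ev, cfg.strategies, schedule, cfg.cv,
        population_label=cfg.label,
        n_random_reps=cfg.n_random_marker_reps,
        re_mob_reps=cfg.re_mob_reps,
        seed=seeds["nre_r"],
    )
    stage_done("strategies")

    if cfg.run_sweep:
        results += run_ts_size_sweep(
            Gp, y, G_ev, y_ev, cfg.core_fractions,
            cfg=cfg.cv, population_label=cfg.label,
            n_random_reps=cfg.n_random_core_reps,
            n_restarts=cfg.core_restarts, seed=seeds["sweep"],
        )
        stage_done("ts_sweep")

    if cfg.run_grid_stage:
        results += run_grid(
            Gp, y, G_ev, y_ev, schedule, cfg.core_fractions,
            cfg=cfg.cv, population_label=cfg.label,
            re_mob_reps=cfg.re_mob_reps, n_restarts=cfg.core_restarts,
            seed=seeds["grid"],
        )
        stage_done("grid")

    frame = results_frame(results)
    frame.to_csv(outdir / "results.tsv", sep="\t", index=False)
    manifest["n_results"] = len(frame)
    manifest["n_markers_pruned"] = Gp.n_markers
    manifest["schedule"] = list(schedule.sizes)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"results": frame, "manifest": manifest}
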
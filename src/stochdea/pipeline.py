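"""The full simulation pipeline: sample, interpret, score, pool.

For every simulation ``j`` and scenario ``i`` the engine draws one
complete dataset realization (all DMUs at once — the DEA frontier is
simulation-wide), optionally interprets it through the fuzzy layer, and
scores every DMU under the requested orientation(s).  Each (j, i) pair
appends ``n_dmu`` records per orientation to the solution pool, so a run
holds ``n_sim * n_sce * n_dmu`` records per orientation.

Both orientations are scored from the same sampled realizations, so
input/output comparisons are paired and Monte-Carlo variance is shared.

Randomness is reproducible: the per-(simulation, scenario) substream is
derived deterministically from the root seed, so runs are exactly
repeatable and scenario-parallelizable.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset import EcosystemDataset, ScenarioSpec, subset_for_scenario
from .dea import DEAProblem, solve_all
from .distribution import RTEPool, StabilityParams
from .exceptions import ConfigurationError
from .fuzzy import FuzzyConfig, interpret_dataset, interpretation_ranges
from .interventions import (ComparisonReport, InterventionSpec,
                            apply_intervention, compare_pools)
from .randomization import RandomizationPlan, Weights, build_plan, \
    sample_realization


@dataclass
class PipelineConfig:
    """Engine configuration for one run."""

    n_sim: int = 500
    orientations: tuple[str, ...] = ("input", "output")
    weights: Weights = field(default_factory=Weights)
    uniform_cells: tuple[tuple[str, str], ...] = ()
    degenerate_cells: tuple[tuple[str, str], ...] = ()
    fuzzy: FuzzyConfig | None = None
    stability: StabilityParams = field(default_factory=StabilityParams)
    seed: int = 0
    phase2: str = "boundary"
    dea_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ConfigurationError("n_sim must be >= 1")
        if not self.orientations:
            raise ConfigurationError("need at least one orientation")
        for o in self.orientations:
            if o not in ("input", "output"):
                raise ConfigurationError(f"unknown orientation {o!r}")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    n_sim: int
    n_sce: int
    n_dmu: int
    n_records_per_orientation: int
    wall_clock_s: dict
    seed: int

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _substream(seed: int, j: int, i: int) -> np.random.Generator:
    """Deterministic per-(simulation, scenario) random stream."""
    return np.random.default_rng(np.random.SeedSequence((seed, j, i)))


def run_pipeline(
    cfg: PipelineConfig,
    ds: EcosystemDataset,
    scenarios: Sequence[ScenarioSpec],
) -> tuple[RTEPool, RunManifest]:
    """Run the Monte-Carlo / fuzzy / DEA pipeline over all scenarios."""
    if not scenarios:
        raise ConfigurationError("need at least one scenario")
    for sc in scenarios:
        sc.validate_against(ds)
    t0 = time.perf_counter()
    plan = build_plan(
        ds,
        uniform_cells=cfg.uniform_cells,
        weights=cfg.weights,
        degenerate_cells=cfg.degenerate_cells,
    )
    timings = {"plan": time.perf_counter() - t0}

    var_names = ds.variable_names
    dmu = ds.dmu_names
    rows: dict[str, list] = {
        "dmu": [], "scenario": [], "simulation": [], "orientation": [],
        "rte": [], "efficiency_class": [],
    }
    t1 = time.perf_counter()
    for j in range(cfg.n_sim):
        for i, sc in enumerate(scenarios):
            rng = _substream(cfg.seed, j, i)
            sampled = sample_realization(plan, rng)
            if cfg.fuzzy is not None:
                ranges = {}
                for r_idx, name in enumerate(dmu):
                    row = dict(zip(var_names, sampled[r_idx]))
                    ranges[name] = interpretation_ranges(ds, cfg.fuzzy, row)
                interpreted = interpret_dataset(
                    sampled, ds, ranges, cfg.fuzzy.profiles
                )
            else:
                interpreted = sampled
            work = ds.replace_values(np.maximum(interpreted, 0.0))
            X, Y = subset_for_scenario(work, sc)
            for orientation in cfg.orientations:
                problem = DEAProblem(X=X, Y=Y, orientation=orientation)
                results = solve_all(problem, tol=cfg.dea_tol, phase2=cfg.phase2)
                for k, res in enumerate(results):
                    rows["dmu"].append(dmu[k])
                    rows["scenario"].append(sc.id)
                    rows["simulation"].append(j)
                    rows["orientation"].append(orientation)
                    rows["rte"].append(res.rte)
                    rows["efficiency_class"].append(res.efficiency_class)
    timings["simulate"] = time.perf_counter() - t1

    import pandas as pd

    pool = RTEPool(pd.DataFrame(rows))
    manifest = RunManifest(
        config={
            "n_sim": cfg.n_sim,
            "orientations": list(cfg.orientations),
            "weights": plan.to_dict()["weights"],
            "uniform_cells": plan.to_dict()["uniform_cells"],
            "degenerate_cells": plan.to_dict()["degenerate_cells"],
            "scenarios": [sc.id for sc in scenarios],
            "fuzzy": cfg.fuzzy is not None,
            "phase2": cfg.phase2,
            "dea_tol": cfg.dea_tol,
        },
        n_sim=cfg.n_sim,
        n_sce=len(scenarios),
        n_dmu=ds.n_dmu,
        n_records_per_orientation=cfg.n_sim * len(scenarios) * ds.n_dmu,
        wall_clock_s=timings,
        seed=cfg.seed,
    )
    return pool, manifest


@dataclass
class InterventionStudy:
    """Pre/post pools and comparison reports of one intervention study."""

    pre_pool: RTEPool
    post_pool: RTEPool
    pre_manifest: RunManifest
    post_manifest: RunManifest
    global_reports: dict[str, ComparisonReport]
    scenario_reports: dict[str, dict[str, ComparisonReport]]
    dmu_reports: dict[str, dict[str, ComparisonReport]]


def run_intervention_study(
    cfg: PipelineConfig,
    ds: EcosystemDataset,
    scenarios: Sequence[ScenarioSpec],
    spec: InterventionSpec,
    populations: Mapping[str, float] | None = None,
    per_dmu: bool = False,
) -> InterventionStudy:
    """Run the pipeline pre and post intervention and compare the pools.

    Both runs use the same seed and configuration, differing only in the
    dataset (and hence the rebuilt randomization plan).  Comparisons are
    produced globally and per scenario for each orientation; per-DMU
    reports are optional (they multiply the report count by ``n_dmu``).
    """
    post_ds = apply_intervention(ds, spec, populations=populations)
    pre_pool, pre_manifest = run_pipeline(cfg, ds, scenarios)
    post_pool, post_manifest = run_pipeline(cfg, post_ds, scenarios)

    global_reports = {}
    scenario_reports: dict[str, dict[str, ComparisonReport]] = {}
    dmu_reports: dict[str, dict[str, ComparisonReport]] = {}
    for orientation in cfg.orientations:
        pre_o = pre_pool.filter(orientation=orientation)
        post_o = post_pool.filter(orientation=orientation)
        global_reports[orientation] = compare_pools(
            pre_o, post_o, unit="Global System", stability=cfg.stability
        )
        scenario_reports[orientation] = {
            sc.id: compare_pools(
                pre_o.filter(scenario=sc.id),
                post_o.filter(scenario=sc.id),
                unit=sc.id,
                stability=cfg.stability,
            )
            for sc in scenarios
        }
        if per_dmu:
            dmu_reports[orientation] = {
                name: compare_pools(
                    pre_o.filter(dmu=name),
                    post_o.filter(dmu=name),
                    unit=name,
                    stability=cfg.stability,
                )
                for name in ds.dmu_names
            }
    return InterventionStudy(
        pre_pool=pre_pool,
        post_pool=post_pool,
        pre_manifest=pre_manifest,
        post_manifest=post_manifest,
        global_reports=global_reports,
        scenario_reports=scenario_reports,
        dmu_reports=dmu_reports,
    )
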
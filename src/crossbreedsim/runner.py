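"""Scenario orchestration: the 27-scenario grid, replicates, seeding, output.

A *scenario* is one combination of within-environment genetic correlation
``r_g`` (-0.4, 0, 0.4), GxE correlation ``r_gxe`` (0.4, 0.6, 0.8) and
selection-index variant (10/30/50% emphasis on tick count).  A *replicate*
builds one founder + burn-in state and runs every requested crossbreeding
strategy from the identical G20 snapshot and farm structure.

Seeding is hierarchical (master seed -> scenario -> replicate -> stage), so
distinct replicates never share RNG streams and any replicate can be
re-run in isolation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import aggregate_replicates, gains_table, generation_summary
from .genome import build_genome_map, simulate_founders
from .population import Herd, IdAllocator
from .programs import (
    ALL_STRATEGIES,
    SCHEMES,
    SYNTHETIC_SCHEMES,
    FarmStructure,
    build_farms,
    continue_exotic,
    initial_cross,
    run_exotic_burnin,
    run_f1_terminal,
    run_local_burnin,
    run_local_nucleus,
    run_rotational,
    run_synthetic,
)
from .scale import PROFILES, REDUCED, ScaleProfile
from .selection import INDEX_SPECS, SelectionIndexSpec
from .traits import EffectMatrix, build_trait_architecture

R_G_VALUES = (-0.4, 0.0, 0.4)
R_GXE_VALUES = (0.4, 0.6, 0.8)
INDEX_LABELS = tuple(INDEX_SPECS)


@dataclass(frozen=True)
class Scenario:
    r_g: float
    r_gxe: float
    index_label: str

    @property
    def label(self) -> str:
        return f"rg{self.r_g:g}_rgxe{self.r_gxe:g}_{self.index_label}"

    @property
    def index_spec(self) -> SelectionIndexSpec:
        return INDEX_SPECS[self.index_label]


def full_grid() -> List[Scenario]:
    """All 27 scenarios (3 genetic correlations x 3 GxE levels x 3 indexes)."""
    return [
        Scenario(rg, rgxe, si)
        for rg in R_G_VALUES
        for rgxe in R_GXE_VALUES
        for si in INDEX_LABELS
    ]


@dataclass
class RunConfig:
    scenarios: Sequence[Scenario] = field(default_factory=full_grid)
    n_replicates: int = 40
    scale: str = "reduced"
    strategies: Sequence[str] = ALL_STRATEGIES
    master_seed: int = 0
    output_dir: str = "results"

    @property
    def profile(self) -> ScaleProfile:
        return PROFILES[self.scale]


@dataclass
class ReplicateState:
    """Shared burn-in state of one replicate (identical for all strategies)."""

    scenario: Scenario
    replicate: int
    profile: ScaleProfile
    gmap: object
    effects: EffectMatrix
    h2_realized: np.ndarray
    local: Herd
    exotic: Herd
    exotic_models: Dict[int, object]
    farms: FarmStructure
    g21: Herd
    strategy_seeds: Dict[str, np.random.SeedSequence]


def _stage_seeds(
    master_seed: int, scenario_index: int, replicate: int
) -> Dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(scenario_index, replicate)
    )
    names = [
        "map", "founders", "traits", "local_burnin", "exotic_burnin",
        "farms", "g21", "nucleus",
    ] + [f"strategy:{s}" for s in ALL_STRATEGIES]
    return dict(zip(names, root.spawn(len(names))))


def prepare_replicate(
    scenario: Scenario,
    replicate: int,
    profile: ScaleProfile = REDUCED,
    master_seed: int = 0,
    scenario_index: int = 0,
    exotic_to: Optional[int] = None,
) -> ReplicateState:
    """Founders, trait architecture, both burn-ins, farms and the initial
    cross — everything the strategies share within a replicate.

    ``exotic_to`` continues the exotic nucleus past G20 (needed by the F1
    and rotational strategies, which import exotic semen every generation).
    """
    seeds = _stage_seeds(master_seed, scenario_index, replicate)
    ids = IdAllocator()
    gmap = build_genome_map(
        seeds["map"],
        n_chromosomes=profile.n_chromosomes,
        qtl_per_chromosome=profile.qtl_per_chromosome,
        snp_per_chromosome=profile.snp_per_chromosome,
    )
    local0, exotic0 = simulate_founders(
        gmap,
        seed=seeds["founders"],
        n_females=profile.founder_females,
        n_males=profile.founder_males,
        ids=ids,
    )
    effects, h2 = build_trait_architecture(
        gmap, local0, exotic0, scenario.r_g, scenario.r_gxe, seeds["traits"]
    )
    local = run_local_burnin(
        local0, effects, gmap, profile, np.random.default_rng(seeds["local_burnin"]), ids
    )
    exotic, models = run_exotic_burnin(
        exotic0, effects, gmap, profile, np.random.default_rng(seeds["exotic_burnin"]), ids
    )
    if exotic_to is not None and exotic_to > profile.burnin_generations:
        exotic, models = continue_exotic(
            exotic, models, effects, gmap, profile,
            np.random.default_rng(seeds["exotic_burnin"]), ids, exotic_to,
        )
    farms = build_farms(local, profile, np.random.default_rng(seeds["farms"]))
    g21 = initial_cross(
        farms, exotic, effects, gmap, profile,
        np.random.default_rng(seeds["g21"]), ids,
    )
    return ReplicateState(
        scenario=scenario,
        replicate=replicate,
        profile=profile,
        gmap=gmap,
        effects=effects,
        h2_realized=h2,
        local=local,
        exotic=exotic,
        exotic_models=models,
        farms=farms,
        g21=g21,
        strategy_seeds={
            **{s: seeds[f"strategy:{s}"] for s in ALL_STRATEGIES},
            "nucleus": seeds["nucleus"],
        },
    )


def run_strategy(state: ReplicateState, name: str) -> Dict[str, Herd]:
    """Run one crossbreeding strategy from the shared G20/G21 state.

    Returns the crossbred population(s) covering G21..G40 keyed by
    population label; the F1 strategy additionally yields the maintained
    pure local line (label "LOC").
    """
    profile = state.profile
    # ids start in disjoint blocks so strategies never reuse identifiers
    offset = 10_000_000 * (1 + list(ALL_STRATEGIES).index(name))
    ids = IdAllocator(offset)
    rng = np.random.default_rng(state.strategy_seeds[name])
    spec = state.scenario.index_spec
    if name in SYNTHETIC_SCHEMES:
        pop = run_synthetic(
            SCHEMES[name], state.farms, state.g21, spec, state.effects,
            state.gmap, profile, rng, ids,
        )
        return {name: pop}
    if name == "ROT":
        nucleus = run_local_nucleus(
            state.local, state.effects, state.gmap, profile,
            np.random.default_rng(state.strategy_seeds["nucleus"]), ids,
        )
        pop = run_rotational(
            state.farms, state.g21, nucleus, state.exotic, state.exotic_models,
            spec, state.effects, state.gmap, profile, rng, ids,
        )
        return {name: pop}
    if name == "F1":
        f1, local_line = run_f1_terminal(
            state.farms, state.local, state.exotic, state.exotic_models,
            state.effects, state.gmap, profile, rng, ids,
        )
        return {"F1": f1, "LOC": local_line}
    raise ValueError(f"unknown strategy {name!r}")


def run_replicate(
    scenario: Scenario,
    replicate: int,
    config: RunConfig,
    scenario_index: int = 0,
) -> pd.DataFrame:
    """One replicate: shared burn-in, then every configured strategy.

    Emits the per-generation metric table over the crossbreeding
    generations (G21..G40) for each strategy population.
    """
    needs_late_exotic = any(s in ("F1", "ROT") for s in config.strategies)
    profile = config.profile
    state = prepare_replicate(
        scenario,
        replicate,
        profile,
        config.master_seed,
        scenario_index,
        exotic_to=profile.final_generation if needs_late_exotic else None,
    )
    gens = range(
        profile.burnin_generations + 1, profile.final_generation + 1
    )
    frames = []
    for name in config.strategies:
        for label, pop in run_strategy(state, name).items():
            frames.append(
                generation_summary(
                    pop, state.effects, state.gmap,
                    strategy=label, scenario=scenario.label,
                    replicate=replicate, generations=list(gens),
                )
            )
    return pd.concat(frames, ignore_index=True)


def run_grid(config: RunConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Iterate scenarios x replicates, aggregate, and write result tables.

    Per-replicate raw tables are written as they finish, so an interrupted
    grid resumes by skipping replicates whose output file already exists.
    Returns (raw, aggregated) tables.
    """
    raw_dir = os.path.join(config.output_dir, "raw")
    os.makedirs(raw_dir, exist_ok=True)
    frames = []
    for si, scenario in enumerate(config.scenarios):
        for rep in range(config.n_replicates):
            path = os.path.join(
                raw_dir, f"{scenario.label}_rep{rep}.csv".replace("%", "pct")
            )
            if os.path.exists(path):
                frames.append(pd.read_csv(path))
                continue
            df = run_replicate(scenario, rep, config, scenario_index=si)
            df.to_csv(path, index=False)
            frames.append(df)
    raw = pd.concat(frames, ignore_index=True)
    agg = aggregate_replicates(raw)
    gains = gains_table(raw)
    raw.to_csv(os.path.join(config.output_dir, "generation_metrics.csv"), index=False)
    agg.to_csv(os.path.join(config.output_dir, "aggregated_metrics.csv"), index=False)
    gains.to_csv(os.path.join(config.output_dir, "gains.csv"), index=False)
    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "scale": config.scale,
        "n_replicates": config.n_replicates,
        "strategies": list(config.strategies),
        "scenarios": [s.label for s in config.scenarios],
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return raw, agg
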
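"""Breeding programs: burn-ins, nucleus herds, farms, and the six
crossbreeding strategies.

Timeline (generation indices):

* G0            founders of both breeds
* G1  – G20     separate pure-breeding burn-ins (local: phenotypic selection
                on tick-count incidence; exotic: RR-BLUP genomic selection on
                body weight)
* G21           initial cross: exotic bulls on the local cows of 200
                smallholder farms (10 villages)
* G22 – G40     one of six strategies: terminal F1 (with a maintained local
                line), two-breed rotation, or a synthetic breed under the
                farm-bull (FB), intra-village-bull (IVB), exchanged-village-
                bull (EVB) or population-wide-bull (PWB) scheme

Within a replicate every strategy starts from the identical burn-in state
and the identical farm structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import MatingPlan, balanced_sexes, make_offspring, phenotype_cohort
from .genome import GenomeMap
from .population import (
    BREED_CROSS,
    BREED_LOCAL,
    FEMALE,
    MALE,
    Herd,
    IdAllocator,
)
from .scale import ScaleProfile
from .selection import (
    EbvModel,
    SelectionIndexSpec,
    fit_rrblup,
    index_of_herd,
    select_top,
    select_with_window,
    window_candidates,
)
from .traits import BW_E, TC_L, EffectMatrix

SYNTHETIC_SCHEMES = ("FB", "IVB", "EVB", "PWB")
ALL_STRATEGIES = ("F1", "ROT") + SYNTHETIC_SCHEMES


@dataclass(frozen=True)
class SchemeConfig:
    """Bull-selection/allocation rules of one synthetic scheme."""

    name: str
    bull_pool: str  # "farm" | "village" | "global"
    allocation: str  # "own-farm" | "own-village" | "derangement-village" | "global"


SCHEMES: Dict[str, SchemeConfig] = {
    "FB": SchemeConfig("FB", "farm", "own-farm"),
    "IVB": SchemeConfig("IVB", "village", "own-village"),
    "EVB": SchemeConfig("EVB", "village", "derangement-village"),
    "PWB": SchemeConfig("PWB", "global", "global"),
}


@dataclass
class FarmStructure:
    """200 smallholder farms in 10 villages with fixed herd sizes.

    ``foundresses`` are the local cows allocated to the farms at G20; the
    assignment is frozen for the replicate and shared by all strategies.
    """

    herd_size: np.ndarray  # (n_farms,)
    village_of: np.ndarray  # (n_farms,)
    foundresses: Herd

    @property
    def n_farms(self) -> int:
        return self.herd_size.size

    @property
    def n_villages(self) -> int:
        return int(self.village_of.max()) + 1

    @property
    def total_cows(self) -> int:
        return int(self.herd_size.sum())


# ---------------------------------------------------------------------------
# Pure-breeding burn-ins
# ---------------------------------------------------------------------------

def run_local_burnin(
    founders_local: Herd,
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
) -> Herd:
    """Expand and select the local breed for 20 generations.

    During the first five generations every available cow is mated (random
    mating to the selected bulls), which grows the population towards the
    cohort cap; afterwards the best cows on tick-count phenotype are
    selected.  Cows come from the last five cohorts, bulls (selected on
    TC_L phenotype) from the last two.
    """
    pop = phenotype_cohort(founders_local, effects, "local", rng)
    history = [pop]
    full = pop
    for g in range(1, profile.burnin_generations + 1):
        cows = window_candidates(full, FEMALE, g - 1, profile.cow_window)
        if g <= profile.expansion_generations:
            if cows.n > profile.local_cohort:
                keep = rng.choice(cows.n, size=profile.local_cohort, replace=False)
                dams = cows.subset(np.sort(keep))
            else:
                dams = cows
        else:
            dams = cows.subset(
                select_top(
                    cows.phenotypes[:, TC_L], cows.ids, profile.local_cohort,
                    context=f"local burn-in cows G{g}",
                )
            )
        sires = select_with_window(
            full, "phenotype", profile.local_bulls, MALE, g - 1,
            profile.bull_window, trait=TC_L, context=f"local burn-in bulls G{g}",
        )
        plan = MatingPlan(
            dam_index=np.arange(dams.n, dtype=np.intp),
            sire_index=rng.integers(0, sires.n, size=dams.n).astype(np.intp),
        )
        cohort = make_offspring(dams, sires, plan, gmap, g, ids, rng, breed=BREED_LOCAL)
        phenotype_cohort(cohort, effects, "local", rng)
        history.append(cohort)
        full = Herd.concat(history)
    return full


def run_exotic_burnin(
    founders_exotic: Herd,
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    n_generations: Optional[int] = None,
) -> Tuple[Herd, Dict[int, EbvModel]]:
    """Run the exotic breed under RR-BLUP selection for body weight.

    Each generation a marker-effect model is trained on all animals of the
    last five cohorts; the top cows (five-generation window) and bulls
    (two-generation window) on EBV are randomly mated.  Returns the full
    history and the per-generation EBV models (``models[g]`` was used to
    produce cohort ``g``).
    """
    n_generations = n_generations or profile.burnin_generations
    pop = phenotype_cohort(founders_exotic, effects, "exotic", rng)
    full = pop
    models: Dict[int, EbvModel] = {}
    full, models = _exotic_generations(
        full, models, effects, gmap, profile, rng, ids, 1, n_generations
    )
    return full, models


def continue_exotic(
    full: Herd,
    models: Dict[int, EbvModel],
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    to_generation: int,
) -> Tuple[Herd, Dict[int, EbvModel]]:
    """Continue the exotic nucleus past the burn-in (to supply cross sires)."""
    start = int(full.gen.max()) + 1
    return _exotic_generations(
        full, models, effects, gmap, profile, rng, ids, start, to_generation
    )


def _exotic_generations(
    full: Herd,
    models: Dict[int, EbvModel],
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    from_gen: int,
    to_gen: int,
) -> Tuple[Herd, Dict[int, EbvModel]]:
    history = [full]
    for g in range(from_gen, to_gen + 1):
        training = window_candidates(full, FEMALE, g - 1, profile.ebv_training_window)
        training = Herd.concat(
            [training, window_candidates(full, MALE, g - 1, profile.ebv_training_window)]
        )
        model = fit_rrblup(training, gmap, trait=BW_E, h2=0.3)
        models[g] = model
        n_cows = min(profile.exotic_cohort, window_candidates(
            full, FEMALE, g - 1, profile.cow_window).n)
        dams = select_with_window(
            full, "ebv", n_cows, FEMALE, g - 1, profile.cow_window,
            model=model, context=f"exotic cows G{g}",
        )
        sires = select_with_window(
            full, "ebv", profile.exotic_bulls, MALE, g - 1, profile.bull_window,
            model=model, context=f"exotic bulls G{g}",
        )
        plan = MatingPlan(
            dam_index=np.arange(dams.n, dtype=np.intp),
            sire_index=rng.integers(0, sires.n, size=dams.n).astype(np.intp),
        )
        cohort = make_offspring(dams, sires, plan, gmap, g, ids, rng)
        phenotype_cohort(cohort, effects, "exotic", rng)
        history.append(cohort)
        full = Herd.concat(history)
        history = [full]
    return full, models


# ---------------------------------------------------------------------------
# Smallholder farm structure
# ---------------------------------------------------------------------------

def build_farms(
    local_history: Herd,
    profile: ScaleProfile,
    rng: np.random.Generator,
    max_resamples: int = 1000,
) -> FarmStructure:
    """Sample farm herd sizes, allocate farms to villages, and place cows.

    Herd sizes are Uniform{herd_min..herd_max}; the whole size vector is
    resampled until the total falls in the accepted range.  Foundress cows
    are drawn without replacement from the most recent local cohorts
    (starting at G20 and reaching back only as far as needed), assigned to
    farms at random, and frozen for the replicate.
    """
    for _ in range(max_resamples):
        sizes = rng.integers(profile.herd_min, profile.herd_max + 1, size=profile.n_farms)
        if profile.total_cows_min <= sizes.sum() <= profile.total_cows_max:
            break
    else:  # pragma: no cover - acceptance probability is far above 1/1000
        raise RuntimeError("failed to draw an admissible farm-size vector")
    total = int(sizes.sum())
    g20 = int(local_history.gen.max())
    back = 1
    pool = local_history.subset(
        (local_history.sex == FEMALE) & (local_history.gen == g20)
    )
    while pool.n < total:
        back += 1
        pool = local_history.subset(
            (local_history.sex == FEMALE) & (local_history.gen > g20 - back)
        )
        if back > profile.cow_window:
            raise ValueError("not enough local cows to populate the farms")
    chosen = pool.subset(np.sort(rng.choice(pool.n, size=total, replace=False)))
    farm_of_cow = rng.permutation(np.repeat(np.arange(profile.n_farms), sizes))
    village_of = np.repeat(
        np.arange(profile.n_villages), profile.farms_per_village
    ).astype(np.int32)
    village_of = rng.permutation(village_of)
    chosen.farm = farm_of_cow.astype(np.int32)
    chosen.village = village_of[farm_of_cow]
    return FarmStructure(
        herd_size=sizes.astype(np.int64), village_of=village_of, foundresses=chosen
    )


def _partition_farms(farm_ids: np.ndarray, n_bulls: int, rng: np.random.Generator) -> np.ndarray:
    """Map each farm to one of ``n_bulls`` bull slots in nearly equal shares."""
    order = rng.permutation(farm_ids)
    slot = np.empty(farm_ids.max() + 1, dtype=np.intp)
    for k, farm in enumerate(order):
        slot[farm] = k % n_bulls
    return slot


def _sexes_by_farm(farm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact 50/50 sexing within each farm's offspring group."""
    out = np.empty(farm.size, dtype=np.uint8)
    for f in np.unique(farm):
        idx = np.flatnonzero(farm == f)
        out[idx] = balanced_sexes(idx.size, rng)
    return out


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


# ---------------------------------------------------------------------------
# Initial cross (G21)
# ---------------------------------------------------------------------------

def initial_cross(
    farms: FarmStructure,
    exotic_history: Herd,
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
) -> Herd:
    """Mate every farm cow to an EBV-selected exotic bull -> G21 crossbreds.

    The top bulls (two-generation window at G20, ranked on a marker model
    trained on the last five exotic cohorts) are split evenly over villages;
    within a village each bull's semen serves ``farms_per_bull`` farms.
    Every cow produces one offspring, phenotyped in the local environment.
    """
    g20 = profile.burnin_generations
    n_bulls = profile.village_bulls * farms.n_villages
    training = Herd.concat(
        [
            window_candidates(exotic_history, FEMALE, g20, profile.ebv_training_window),
            window_candidates(exotic_history, MALE, g20, profile.ebv_training_window),
        ]
    )
    model = fit_rrblup(training, gmap, trait=BW_E, h2=0.3)
    bulls = select_with_window(
        exotic_history, "ebv", n_bulls, MALE, g20, profile.bull_window,
        model=model, context="initial-cross exotic bulls",
    )
    sire_of_farm = _allocate_village_bulls(
        farms, np.arange(n_bulls), profile, rng, village_map=None
    )
    dams = farms.foundresses
    plan = MatingPlan(
        dam_index=np.arange(dams.n, dtype=np.intp),
        sire_index=sire_of_farm[dams.farm].astype(np.intp),
    )
    cohort = make_offspring(
        dams, bulls, plan, gmap, g20 + 1, ids, rng, breed=BREED_CROSS,
        farm=dams.farm, village=dams.village,
        sexes=_sexes_by_farm(dams.farm, rng),
    )
    return phenotype_cohort(cohort, effects, "local", rng)


def _allocate_village_bulls(
    farms: FarmStructure,
    bull_slots: np.ndarray,
    profile: ScaleProfile,
    rng: np.random.Generator,
    village_map: Optional[np.ndarray],
) -> np.ndarray:
    """Farm -> bull-slot map when ``village_bulls`` bulls serve each village.

    ``bull_slots`` is laid out village-major: slots [v * village_bulls,
    (v+1) * village_bulls) belong to village v (the *source* village).  With
    ``village_map`` given (EVB), bulls from village v serve the farms of
    village_map[v]; otherwise bulls serve their own village.
    """
    sire_of_farm = np.empty(farms.n_farms, dtype=np.intp)
    for v in range(farms.n_villages):
        target = v if village_map is None else int(np.flatnonzero(village_map == v)[0])
        # farms of village v are served by bulls sourced from village `target`
        farm_ids = np.flatnonzero(farms.village_of == v)
        local_slot = _partition_farms(farm_ids, profile.village_bulls, rng)
        sire_of_farm[farm_ids] = (
            target * profile.village_bulls + local_slot[farm_ids]
        )
    return sire_of_farm


# ---------------------------------------------------------------------------
# Crossbred cow selection (shared by synthetic and rotational programs)
# ---------------------------------------------------------------------------

def _select_farm_dams(
    pool: Herd,
    farms: FarmStructure,
    g: int,
    profile: ScaleProfile,
    rank_values: np.ndarray,
) -> Herd:
    """Per farm, the best females of the last five cohorts, up to herd size.

    In the first crossbred generations fewer females than the herd size may
    exist; the shortfall is tolerated (the cohort recovers as the
    five-generation window fills).
    """
    lo = g - profile.cow_window
    mask = (pool.sex == FEMALE) & (pool.gen >= lo) & (pool.gen <= g - 1)
    picks: List[np.ndarray] = []
    for f in range(farms.n_farms):
        idx = np.flatnonzero(mask & (pool.farm == f))
        if idx.size == 0:
            raise ValueError(f"farm {f} has no eligible cows at G{g}")
        take = min(int(farms.herd_size[f]), idx.size)
        top = select_top(rank_values[idx], pool.ids[idx], take)
        picks.append(idx[top])
    return pool.subset(np.concatenate(picks))


def _farm_cohort(
    dams: Herd,
    bulls: Herd,
    sire_of_farm: np.ndarray,
    effects: EffectMatrix,
    gmap: GenomeMap,
    g: int,
    ids: IdAllocator,
    rng: np.random.Generator,
) -> Herd:
    plan = MatingPlan(
        dam_index=np.arange(dams.n, dtype=np.intp),
        sire_index=sire_of_farm[dams.farm].astype(np.intp),
    )
    cohort = make_offspring(
        dams, bulls, plan, gmap, g, ids, rng, breed=BREED_CROSS,
        farm=dams.farm, village=dams.village,
        sexes=_sexes_by_farm(dams.farm, rng),
    )
    return phenotype_cohort(cohort, effects, "local", rng)


# ---------------------------------------------------------------------------
# Synthetic schemes (FB / IVB / EVB / PWB)
# ---------------------------------------------------------------------------

def run_synthetic(
    scheme: SchemeConfig,
    farms: FarmStructure,
    g21: Herd,
    index_spec: SelectionIndexSpec,
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    n_generations: Optional[int] = None,
) -> Herd:
    """Closed crossbred population under one bull-selection/allocation rule.

    Each generation, candidate bulls from the last two cohorts are ranked on
    the selection index within the scheme's pool (farm, village or whole
    population) and allocated to farms per the scheme; each farm's best
    index cows (five-cohort window) each produce one offspring.
    """
    n_generations = n_generations or profile.cross_generations
    g_start = int(g21.gen.max())
    pop = g21
    for g in range(g_start + 1, g_start + n_generations + 1):
        index_vals = index_of_herd(pop, index_spec)
        bull_mask = (pop.sex == MALE) & (pop.gen >= g - profile.bull_window) & (
            pop.gen <= g - 1
        )
        if scheme.bull_pool == "farm":
            bull_idx = []
            for f in range(farms.n_farms):
                idx = np.flatnonzero(bull_mask & (pop.farm == f))
                if idx.size == 0:
                    raise ValueError(
                        f"{scheme.name}: farm {f} has no bull candidate at G{g}"
                    )
                top = select_top(index_vals[idx], pop.ids[idx], 1)
                bull_idx.append(idx[top])
            bulls = pop.subset(np.concatenate(bull_idx))
            sire_of_farm = np.arange(farms.n_farms, dtype=np.intp)
        elif scheme.bull_pool == "village":
            bull_idx = []
            for v in range(farms.n_villages):
                idx = np.flatnonzero(bull_mask & (pop.village == v))
                if idx.size < profile.village_bulls:
                    raise ValueError(
                        f"{scheme.name}: village {v} has {idx.size} bull "
                        f"candidates for {profile.village_bulls} slots at G{g}"
                    )
                top = select_top(index_vals[idx], pop.ids[idx], profile.village_bulls)
                bull_idx.append(idx[top])
            bulls = pop.subset(np.concatenate(bull_idx))
            village_map = (
                _random_derangement(farms.n_villages, rng)
                if scheme.allocation == "derangement-village"
                else None
            )
            sire_of_farm = _allocate_village_bulls(
                farms, np.arange(bulls.n), profile, rng, village_map
            )
        else:  # global pool (PWB)
            idx = np.flatnonzero(bull_mask)
            if idx.size < profile.pwb_bulls:
                raise ValueError(
                    f"{scheme.name}: {idx.size} bull candidates for "
                    f"{profile.pwb_bulls} slots at G{g}"
                )
            top = select_top(index_vals[idx], pop.ids[idx], profile.pwb_bulls)
            bulls = pop.subset(idx[top])
            slot = _partition_farms(np.arange(farms.n_farms), profile.pwb_bulls, rng)
            sire_of_farm = slot[: farms.n_farms]
        dams = _select_farm_dams(pop, farms, g, profile, index_vals)
        cohort = _farm_cohort(dams, bulls, sire_of_farm, effects, gmap, g, ids, rng)
        pop = Herd.concat([pop, cohort])
    return pop


# ---------------------------------------------------------------------------
# Rotational crossbreeding
# ---------------------------------------------------------------------------

def run_rotational(
    farms: FarmStructure,
    g21: Herd,
    local_nucleus: Herd,
    exotic_history: Herd,
    exotic_models: Dict[int, EbvModel],
    index_spec: SelectionIndexSpec,
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    n_generations: Optional[int] = None,
) -> Herd:
    """Alternate local-nucleus and exotic-nucleus sires on crossbred cows.

    The initial exotic cross (G21, odd) anchors the parity: even generations
    use local-nucleus bulls (phenotypic TC_L selection), odd generations
    exotic-nucleus bulls (EBV selection).  Bulls come from the source herd's
    last two cohorts; five are assigned per village, each serving four
    farms.  Cows are selected on the index within farms exactly as in the
    synthetic schemes.
    """
    n_generations = n_generations or profile.cross_generations
    g_start = int(g21.gen.max())
    n_bulls = profile.village_bulls * farms.n_villages
    pop = g21
    for g in range(g_start + 1, g_start + n_generations + 1):
        if g % 2 == 0:  # local bulls at even generations
            bulls = select_with_window(
                local_nucleus, "phenotype", n_bulls, MALE, g - 1,
                profile.bull_window, trait=TC_L,
                context=f"rotational local bulls G{g}",
            )
        else:
            bulls = select_with_window(
                exotic_history, "ebv", n_bulls, MALE, g - 1, profile.bull_window,
                model=exotic_models[g], context=f"rotational exotic bulls G{g}",
            )
        sire_of_farm = _allocate_village_bulls(
            farms, np.arange(bulls.n), profile, rng, village_map=None
        )
        index_vals = index_of_herd(pop, index_spec)
        dams = _select_farm_dams(pop, farms, g, profile, index_vals)
        cohort = _farm_cohort(dams, bulls, sire_of_farm, effects, gmap, g, ids, rng)
        pop = Herd.concat([pop, cohort])
    return pop


# ---------------------------------------------------------------------------
# Terminal F1 with a maintained local line
# ---------------------------------------------------------------------------

def run_f1_terminal(
    farms: FarmStructure,
    local_history: Herd,
    exotic_history: Herd,
    exotic_models: Dict[int, EbvModel],
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    n_generations: Optional[int] = None,
) -> Tuple[Herd, Herd]:
    """Terminal F1 production over a pure local line kept on the farms.

    Each generation the selected local cows (phenotypic TC_L within farm,
    five-cohort window) are mated twice: once to an EBV-selected exotic
    nucleus bull (-> F1, slaughtered, never bred) and once to a local bull
    (-> local replacement).  Local bulls are selected per village from the
    local line's last two cohorts; at the start the burn-in supplies them.

    Returns ``(f1_pop, local_line)`` with generations G21..G40; the local
    line doubles as the pure local comparison population.
    """
    n_generations = (n_generations or profile.cross_generations) + 1  # incl. G21
    g20 = profile.burnin_generations
    n_bulls = profile.village_bulls * farms.n_villages
    # local line lives on the farms; foundresses keep their original cohorts
    local_line = farms.foundresses
    f1_parts: List[Herd] = []
    local_parts: List[Herd] = []
    for g in range(g20 + 1, g20 + n_generations + 1):
        dams = _select_farm_dams(
            local_line, farms, g, profile, local_line.phenotypes[:, TC_L]
        )
        # exotic sires for the F1 cross
        exotic_bulls = select_with_window(
            exotic_history, "ebv", n_bulls, MALE, g - 1, profile.bull_window,
            model=exotic_models[g], context=f"F1 exotic bulls G{g}",
        )
        sire_of_farm = _allocate_village_bulls(
            farms, np.arange(exotic_bulls.n), profile, rng, village_map=None
        )
        f1 = _farm_cohort(
            dams, exotic_bulls, sire_of_farm, effects, gmap, g, ids, rng
        )
        f1_parts.append(f1)
        # local sires for the replacement line
        bull_source = local_history if g == g20 + 1 else local_line
        local_bull_idx: List[np.ndarray] = []
        bmask = (
            (bull_source.sex == MALE)
            & (bull_source.gen >= g - profile.bull_window)
            & (bull_source.gen <= g - 1)
        )
        for v in range(farms.n_villages):
            if g == g20 + 1:
                idx = np.flatnonzero(bmask)  # burn-in males carry no village
            else:
                idx = np.flatnonzero(bmask & (bull_source.village == v))
            if idx.size < profile.village_bulls:
                raise ValueError(
                    f"F1 local line: village {v} lacks bull candidates at G{g}"
                )
            top = select_top(
                bull_source.phenotypes[idx, TC_L], bull_source.ids[idx],
                profile.village_bulls,
            )
            local_bull_idx.append(idx[top])
        local_bulls = bull_source.subset(np.concatenate(local_bull_idx))
        sire_of_farm = _allocate_village_bulls(
            farms, np.arange(local_bulls.n), profile, rng, village_map=None
        )
        plan = MatingPlan(
            dam_index=np.arange(dams.n, dtype=np.intp),
            sire_index=sire_of_farm[dams.farm].astype(np.intp),
        )
        replacement = make_offspring(
            dams, local_bulls, plan, gmap, g, ids, rng, breed=BREED_LOCAL,
            farm=dams.farm, village=dams.village,
            sexes=_sexes_by_farm(dams.farm, rng),
        )
        phenotype_cohort(replacement, effects, "local", rng)
        local_parts.append(replacement)
        local_line = Herd.concat([local_line, replacement])
    return Herd.concat(f1_parts), Herd.concat(local_parts)


# ---------------------------------------------------------------------------
# Local nucleus herd (rotational sire source)
# ---------------------------------------------------------------------------

def run_local_nucleus(
    local_history: Herd,
    effects: EffectMatrix,
    gmap: GenomeMap,
    profile: ScaleProfile,
    rng: np.random.Generator,
    ids: IdAllocator,
    n_generations: Optional[int] = None,
) -> Herd:
    """Closed government herd preserving the local breed on TC_L phenotype.

    Founded from the best cows of burn-in cohorts G16–G19 (and bulls from
    the last two burn-in cohorts); thereafter 2000 cows and 50 bulls are
    selected each generation within the nucleus.
    """
    n_generations = (n_generations or profile.cross_generations) + 1
    g20 = profile.burnin_generations
    fem = local_history.subset(
        (local_history.sex == FEMALE)
        & (local_history.gen >= g20 - 4)
        & (local_history.gen <= g20 - 1)
    )
    cows = fem.subset(
        select_top(fem.phenotypes[:, TC_L], fem.ids, profile.nucleus_cows,
                   context="nucleus founding cows")
    )
    bulls = select_with_window(
        local_history, "phenotype", profile.nucleus_bulls, MALE, g20,
        profile.bull_window, trait=TC_L, context="nucleus founding bulls",
    )
    nucleus = Herd.concat([cows, bulls])
    for g in range(g20 + 1, g20 + n_generations + 1):
        dams_pool = window_candidates(nucleus, FEMALE, g - 1, profile.cow_window)
        n_dams = min(profile.nucleus_cows, dams_pool.n)
        dams = dams_pool.subset(
            select_top(dams_pool.phenotypes[:, TC_L], dams_pool.ids, n_dams)
        )
        sires = select_with_window(
            nucleus, "phenotype", profile.nucleus_bulls, MALE, g - 1,
            profile.bull_window, trait=TC_L, context=f"nucleus bulls G{g}",
        )
        plan = MatingPlan(
            dam_index=np.arange(dams.n, dtype=np.intp),
            sire_index=rng.integers(0, sires.n, size=dams.n).astype(np.intp),
        )
        cohort = make_offspring(dams, sires, plan, gmap, g, ids, rng, breed=BREED_LOCAL)
        phenotype_cohort(cohort, effects, "local", rng)
        nucleus = Herd.concat([nucleus, cohort])
    return nucleus
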
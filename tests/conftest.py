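"""Shared fixtures: a tiny genome, small founder herds, and a miniature
scale profile for fast structural tests of the breeding programs."""

import pytest

from crossbreedsim.genome import build_genome_map, simulate_founders
from crossbreedsim.population import IdAllocator
from crossbreedsim.scale import ScaleProfile
from crossbreedsim.traits import build_trait_architecture


@pytest.fixture(scope="session")
def tiny_map():
    return build_genome_map(
        seed=11, n_chromosomes=2, qtl_per_chromosome=10, snp_per_chromosome=20
    )


@pytest.fixture(scope="session")
def small_map():
    return build_genome_map(
        seed=13, n_chromosomes=5, qtl_per_chromosome=30, snp_per_chromosome=80
    )


@pytest.fixture(scope="session")
def small_founders(small_map):
    return simulate_founders(
        small_map, seed=17, n_females=200, n_males=50, ids=IdAllocator()
    )


@pytest.fixture(scope="session")
def small_effects(small_map, small_founders):
    local, exotic = small_founders
    effects, h2 = build_trait_architecture(
        small_map, local, exotic, r_g=0.0, r_gxe=0.6, seed=23
    )
    return effects


#: miniature profile: every structural ratio of the full design (farms per
#: village, farms served per bull, windows) at the smallest size that keeps
#: all selection steps feasible
MINI = ScaleProfile(
    name="mini",
    n_chromosomes=4,
    qtl_per_chromosome=20,
    snp_per_chromosome=50,
    founder_females=120,
    founder_males=30,
    local_cohort=240,
    local_bulls=6,
    exotic_cohort=120,
    exotic_bulls=4,
    nucleus_cows=60,
    nucleus_bulls=3,
    n_farms=8,
    n_villages=2,
    herd_min=8,
    herd_max=40,
    total_cows_min=160,
    total_cows_max=200,
    village_bulls=1,
    pwb_bulls=2,
    farms_per_bull=4,
    expansion_generations=5,
    burnin_generations=20,
    cross_generations=19,
    cow_window=5,
    bull_window=2,
    ebv_training_window=5,
)


@pytest.fixture(scope="session")
def mini_profile():
    return MINI
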
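"""Population-size profiles.

``FULL`` mirrors the smallholder crossbreeding study design: a 30-chromosome
genome, 10,000 local and 2,000 exotic animals per burn-in generation, 200
farms in 10 villages.  ``REDUCED`` preserves every structural ratio
(bulls : cows, farms : villages, farms served per bull, selection windows)
at roughly one tenth of the animal numbers and one fifth of the genome, so a
replicate runs in seconds-to-minutes on one CPU while keeping per-farm herd
sizes — and therefore within-farm drift and inbreeding dynamics — identical
to the full design.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleProfile:
    name: str
    # genome
    n_chromosomes: int
    qtl_per_chromosome: int
    snp_per_chromosome: int
    # founders (per breed)
    founder_females: int
    founder_males: int
    # pure-breeding burn-ins
    local_cohort: int
    local_bulls: int
    exotic_cohort: int
    exotic_bulls: int
    # nucleus herds
    nucleus_cows: int
    nucleus_bulls: int
    # smallholder structure
    n_farms: int
    n_villages: int
    herd_min: int
    herd_max: int
    total_cows_min: int
    total_cows_max: int
    village_bulls: int  # bulls allocated per village (IVB/EVB/rotational/F1)
    pwb_bulls: int  # global bulls in the population-wide scheme
    farms_per_bull: int
    # timing
    expansion_generations: int
    burnin_generations: int
    cross_generations: int
    # selection windows (generations)
    cow_window: int
    bull_window: int
    ebv_training_window: int

    @property
    def farms_per_village(self) -> int:
        return self.n_farms // self.n_villages

    @property
    def final_generation(self) -> int:
        return self.burnin_generations + 1 + self.cross_generations


FULL = ScaleProfile(
    name="full",
    n_chromosomes=30,
    qtl_per_chromosome=300,
    snp_per_chromosome=1400,
    founder_females=2000,
    founder_males=500,
    local_cohort=10_000,
    local_bulls=200,
    exotic_cohort=2000,
    exotic_bulls=50,
    nucleus_cows=2000,
    nucleus_bulls=50,
    n_farms=200,
    n_villages=10,
    herd_min=8,
    herd_max=40,
    total_cows_min=4000,
    total_cows_max=5000,
    village_bulls=5,
    pwb_bulls=50,
    farms_per_bull=4,
    expansion_generations=5,
    burnin_generations=20,
    cross_generations=19,
    cow_window=5,
    bull_window=2,
    ebv_training_window=5,
)

REDUCED = ScaleProfile(
    name="reduced",
    n_chromosomes=10,
    qtl_per_chromosome=60,
    snp_per_chromosome=280,
    founder_females=400,
    founder_males=100,
    local_cohort=1000,
    local_bulls=20,
    exotic_cohort=400,
    exotic_bulls=10,
    nucleus_cows=200,
    nucleus_bulls=5,
    n_farms=40,
    n_villages=5,
    herd_min=8,
    herd_max=40,
    total_cows_min=800,
    total_cows_max=1000,
    village_bulls=2,
    pwb_bulls=10,
    farms_per_bull=4,
    expansion_generations=5,
    burnin_generations=20,
    cross_generations=19,
    cow_window=5,
    bull_window=2,
    ebv_training_window=5,
)

PROFILES = {"full": FULL, "reduced": REDUCED}
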
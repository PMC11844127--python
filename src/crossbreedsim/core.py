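"""Forward-in-time breeding engine: meiosis, mating, sexing, phenotyping.

Recombination follows the Haldane model: per chromosome the crossover count
is Poisson(genetic length in Morgan) with crossover positions uniform and no
interference.  Cohorts are sexed exactly 50/50 (a permuted balanced label
vector rather than Bernoulli draws), which matches the stated cohort
composition and keeps the female supply of very small farm herds stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import GenomeMap
from .population import FEMALE, MALE, Herd, IdAllocator
from .traits import ENV_TRAITS, EffectMatrix, genetic_values


@dataclass
class MatingPlan:
    """Aligned per-offspring parent indices into a dam herd and a sire herd."""

    dam_index: np.ndarray
    sire_index: np.ndarray

    @property
    def n_offspring(self) -> int:
        return self.dam_index.size


def meiosis(
    parent_haplo: np.ndarray, gmap: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete (length n_loci) from a (2, n_loci) parental haplotype pair."""
    return _gametes(parent_haplo[None, :, :], np.zeros(1, dtype=np.intp), gmap, rng)[0]


def _gametes(
    haplo: np.ndarray, parent_index: np.ndarray, gmap: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Batch of gametes, one per entry of ``parent_index`` into ``haplo``.

    For each gamete and chromosome, the transmitted strand starts on a random
    parental haplotype and switches at each crossover (Poisson count, uniform
    positions, Haldane / no interference).
    """
    n = parent_index.size
    out = np.empty((n, gmap.n_loci), dtype=np.uint8)
    length = gmap.genetic_length
    k_loci = gmap.loci_per_chromosome
    counts = rng.poisson(length, size=(n, gmap.n_chromosomes))
    starts = rng.integers(0, 2, size=(n, gmap.n_chromosomes))
    locus_range = np.arange(k_loci)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        pos = gmap.pos[sl]
        for g in range(n):
            p = parent_index[g]
            k = counts[g, c]
            if k == 0:
                out[g, sl] = haplo[p, starts[g, c], sl]
            else:
                xpos = np.sort(rng.uniform(0.0, length, size=k))
                which = (starts[g, c] + np.searchsorted(xpos, pos)) % 2
                out[g, sl] = haplo[p, :, sl][which, locus_range]
    return out


def balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly half male / half female (the extra animal female when n is odd)."""
    sexes = np.full(n, FEMALE, dtype=np.uint8)
    sexes[: n // 2] = MALE
    return rng.permutation(sexes)


def make_offspring(
    dams: Herd,
    sires: Herd,
    plan: MatingPlan,
    gmap: GenomeMap,
    gen: int,
    ids: IdAllocator,
    rng: np.random.Generator,
    breed: Optional[int] = None,
    farm: Optional[np.ndarray] = None,
    village: Optional[np.ndarray] = None,
    sexes: Optional[np.ndarray] = None,
) -> Herd:
    """Produce one offspring per mating-plan row; cohort sexed 50/50.

    Each offspring receives one fresh meiosis from its dam and one from its
    sire; repeated appearances of a sire model repeated semen use.
    """
    if (dams.sex != FEMALE).any():
        raise ValueError("dam herd contains non-female animals")
    if (sires.sex != MALE).any():
        raise ValueError("sire herd contains non-male animals")
    n = plan.n_offspring
    hap_d = _gametes(dams.haplo, plan.dam_index, gmap, rng)
    hap_s = _gametes(sires.haplo, plan.sire_index, gmap, rng)
    haplo = np.stack([hap_d, hap_s], axis=1)
    if sexes is None:
        sexes = balanced_sexes(n, rng)
    if breed is None:
        db = dams.breed[plan.dam_index]
        sb = sires.breed[plan.sire_index]
        breed_arr = np.where(db == sb, db, np.int8(2)).astype(np.int8)
    else:
        breed_arr = np.full(n, breed, dtype=np.int8)
    return Herd(
        haplo=haplo,
        sex=sexes,
        gen=np.full(n, gen, dtype=np.int16),
        ids=ids.take(n),
        sire=sires.ids[plan.sire_index],
        dam=dams.ids[plan.dam_index],
        breed=breed_arr,
        farm=np.full(n, -1, np.int32) if farm is None else np.asarray(farm, np.int32),
        village=np.full(n, -1, np.int32)
        if village is None
        else np.asarray(village, np.int32),
    )


def mate(
    dam: Herd,
    sire: Herd,
    gmap: GenomeMap,
    gen: int,
    ids: IdAllocator,
    rng: np.random.Generator,
) -> Herd:
    """Single offspring from one dam and one sire (sex random)."""
    plan = MatingPlan(np.zeros(1, dtype=np.intp), np.zeros(1, dtype=np.intp))
    sexes = rng.integers(0, 2, size=1).astype(np.uint8)
    return make_offspring(dam, sire, plan, gmap, gen, ids, rng, sexes=sexes)


def phenotype_cohort(
    cohort: Herd,
    effects: EffectMatrix,
    environment: str,
    rng: np.random.Generator,
) -> Herd:
    """Record phenotypes for the traits expressed in ``environment``.

    phenotype = total genetic value + Normal(0, Ve); residuals independent
    across animals and traits.  Traits of the other environment stay NaN.
    """
    if environment not in ENV_TRAITS:
        raise ValueError(f"unknown environment {environment!r}")
    if effects.ve is None:
        raise ValueError("effects must be residual-calibrated before phenotyping")
    _, _, total = genetic_values(cohort, effects)
    cohort.phenotypes[:] = np.nan
    for t in ENV_TRAITS[environment]:
        sd = np.sqrt(effects.ve[t])
        noise = rng.normal(0.0, sd, size=cohort.n) if sd > 0 else 0.0
        cohort.phenotypes[:, t] = total[:, t] + noise
    return cohort


# ---------------------------------------------------------------------------
# Plain-text exports
# ---------------------------------------------------------------------------

def write_pedigree(path, herd: Herd) -> None:
    """Three-column pedigree table (id, sire, dam); -1 marks founders."""
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\n")
        for aid, s, d in zip(herd.ids, herd.sire, herd.dam):
            fh.write(f"{aid}\t{s}\t{d}\n")


def write_phenotypes(path, herd: Herd) -> None:
    """Long-format phenotype table (id, generation, trait, value)."""
    from .traits import TRAIT_NAMES

    with open(path, "w") as fh:
        fh.write("id\tgeneration\ttrait\tvalue\n")
        for i in range(herd.n):
            for t, name in enumerate(TRAIT_NAMES):
                v = herd.phenotypes[i, t]
                if np.isfinite(v):
                    fh.write(f"{herd.ids[i]}\t{herd.gen[i]}\t{name}\t{v:.10g}\n")
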
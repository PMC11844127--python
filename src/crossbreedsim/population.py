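"""In-memory population container used by every stage of the simulator.

A :class:`Herd` is a flat, array-backed collection of animals: two biallelic
haplotypes per animal over a shared genome map, plus sex, cohort index
(generation), pedigree links, breed origin and an optional farm/village
location.  All breeding operators (meiosis, selection, the crossbreeding
schemes) produce and consume Herds, which keeps the forward simulation fully
vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

FEMALE = 0
MALE = 1

BREED_LOCAL = 0
BREED_EXOTIC = 1
BREED_CROSS = 2

BREED_LABELS = {BREED_LOCAL: "local", BREED_EXOTIC: "exotic", BREED_CROSS: "cross"}


class IdAllocator:
    """Monotone supplier of unique animal identifiers within a replicate."""

    def __init__(self, start: int = 0):
        self._next = int(start)

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self._next, self._next + n, dtype=np.int64)
        self._next += n
        return ids


@dataclass
class Herd:
    """Array-of-animals container.

    Attributes
    ----------
    haplo
        uint8 array of shape ``(n, 2, n_loci)`` with 0/1 alleles.
    sex
        0 = female, 1 = male.
    gen
        Cohort (generation) index of each animal.
    ids, sire, dam
        Animal and parent identifiers (-1 for founder parents).
    breed
        0 = local, 1 = exotic, 2 = crossbred.
    farm, village
        Location indices, -1 when the animal is not on a smallholder farm.
    phenotypes
        ``(n, 4)`` float array in trait order (BW_L, TC_L, BW_E, TC_E);
        NaN for traits not expressed in the animal's environment.
    """

    haplo: np.ndarray
    sex: np.ndarray
    gen: np.ndarray
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    breed: np.ndarray
    farm: np.ndarray = field(default=None)  # type: ignore[assignment]
    village: np.ndarray = field(default=None)  # type: ignore[assignment]
    phenotypes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.haplo.shape[0]
        if self.farm is None:
            self.farm = np.full(n, -1, dtype=np.int32)
        if self.village is None:
            self.village = np.full(n, -1, dtype=np.int32)
        if self.phenotypes is None:
            self.phenotypes = np.full((n, 4), np.nan)

    # -- basic shape -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.haplo.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplo.shape[2]

    def __len__(self) -> int:
        return self.n

    # -- genotype views ----------------------------------------------------
    def dosage(self, loci: Optional[np.ndarray] = None) -> np.ndarray:
        """Allele-dosage matrix (n x n_loci), values in {0, 1, 2}."""
        if loci is None:
            return self.haplo.sum(axis=1, dtype=np.uint8)
        return self.haplo[:, :, loci].sum(axis=1, dtype=np.uint8)

    def allele_freq(self, loci: Optional[np.ndarray] = None) -> np.ndarray:
        if self.n == 0:
            raise ValueError("allele frequencies undefined for an empty herd")
        hap = self.haplo if loci is None else self.haplo[:, :, loci]
        return hap.mean(axis=(0, 1))

    # -- selection / combination ------------------------------------------
    def subset(self, index: np.ndarray) -> "Herd":
        return Herd(
            haplo=self.haplo[index],
            sex=self.sex[index],
            gen=self.gen[index],
            ids=self.ids[index],
            sire=self.sire[index],
            dam=self.dam[index],
            breed=self.breed[index],
            farm=self.farm[index],
            village=self.village[index],
            phenotypes=self.phenotypes[index],
        )

    @staticmethod
    def concat(herds: Sequence["Herd"]) -> "Herd":
        herds = [h for h in herds if h.n > 0]
        if not herds:
            raise ValueError("cannot concatenate zero non-empty herds")
        return Herd(
            haplo=np.concatenate([h.haplo for h in herds], axis=0),
            sex=np.concatenate([h.sex for h in herds]),
            gen=np.concatenate([h.gen for h in herds]),
            ids=np.concatenate([h.ids for h in herds]),
            sire=np.concatenate([h.sire for h in herds]),
            dam=np.concatenate([h.dam for h in herds]),
            breed=np.concatenate([h.breed for h in herds]),
            farm=np.concatenate([h.farm for h in herds]),
            village=np.concatenate([h.village for h in herds]),
            phenotypes=np.concatenate([h.phenotypes for h in herds], axis=0),
        )

    def females(self) -> "Herd":
        return self.subset(self.sex == FEMALE)

    def males(self) -> "Herd":
        return self.subset(self.sex == MALE)

    def in_generations(self, generations: Iterable[int]) -> "Herd":
        gens = np.asarray(list(generations))
        return self.subset(np.isin(self.gen, gens))


def herd_from_haplotypes(
    haplo: np.ndarray,
    sex: np.ndarray,
    gen: int,
    ids: np.ndarray,
    breed: int,
    sire: Optional[np.ndarray] = None,
    dam: Optional[np.ndarray] = None,
) -> Herd:
    """Build a founder-style herd (no recorded parents)."""
    n = haplo.shape[0]
    return Herd(
        haplo=np.ascontiguousarray(haplo, dtype=np.uint8),
        sex=np.asarray(sex, dtype=np.uint8),
        gen=np.full(n, gen, dtype=np.int16),
        ids=np.asarray(ids, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64) if sire is None else sire,
        dam=np.full(n, -1, dtype=np.int64) if dam is None else dam,
        breed=np.full(n, breed, dtype=np.int8),
    )
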
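"""Struct-of-arrays population container and world/population setup."""
from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from . import kernels
from .params import SimParams

#: One chromosome: driver/wildtype allele plus the two dispersal loci.
Haplotype = namedtuple("Haplotype", "allele d0 d1")

#: Read-only view of one mouse (``sex`` is "female"/"male", ``genotype``
#: counts t alleles, ``dominant`` is "a" or "b").
MouseView = namedtuple(
    "MouseView", "index sex age patch genotype hap_a hap_b dominant"
)

_ARRAYS = ("sex", "age", "patch", "allele_a", "allele_b",
           "d0a", "d1a", "d0b", "d1b", "dom")


class Population:
    """The living mice, one array entry per individual.

    Arrays: ``sex`` (0 male, 1 female), ``age`` (turns since birth),
    ``patch`` (patch index), ``allele_a``/``allele_b`` (0 = +, 1 = t),
    ``d0a``/``d1a``/``d0b``/``d1b`` (dispersal loci of haplotypes a and b)
    and ``dom`` (0/1, which haplotype is expressed). Row order carries no
    meaning; indices serve as transient identifiers within a turn.
    """

    __slots__ = _ARRAYS

    def __init__(self, sex, age, patch, allele_a, allele_b,
                 d0a, d1a, d0b, d1b, dom):
        self.sex = sex
        self.age = age
        self.patch = patch
        self.allele_a = allele_a
        self.allele_b = allele_b
        self.d0a = d0a
        self.d1a = d1a
        self.d0b = d0b
        self.d1b = d1b
        self.dom = dom

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(cls, arrays) -> "Population":
        return cls(*arrays)

    def arrays(self):
        return tuple(getattr(self, name) for name in _ARRAYS)

    def copy(self) -> "Population":
        return Population(*(a.copy() for a in self.arrays()))

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return self.sex.size

    def mouse(self, i: int) -> MouseView:
        return MouseView(
            index=i,
            sex="female" if self.sex[i] == 1 else "male",
            age=int(self.age[i]),
            patch=int(self.patch[i]),
            genotype=int(self.allele_a[i]) + int(self.allele_b[i]),
            hap_a=Haplotype(int(self.allele_a[i]), float(self.d0a[i]), float(self.d1a[i])),
            hap_b=Haplotype(int(self.allele_b[i]), float(self.d0b[i]), float(self.d1b[i])),
            dominant="a" if self.dom[i] == 0 else "b",
        )

    def genotypes(self) -> np.ndarray:
        """Number of t alleles per mouse (0, 1 or 2)."""
        return self.allele_a.astype(np.int64) + self.allele_b

    def patch_counts(self, n_patches: int) -> np.ndarray:
        return np.bincount(self.patch, minlength=n_patches)

    def chromosome_counts(self) -> tuple[int, int]:
        """(number of + chromosomes, number of t chromosomes) among the living."""
        n_t = int((self.allele_a == kernels.DRIVER).sum()
                  + (self.allele_b == kernels.DRIVER).sum())
        return 2 * len(self) - n_t, n_t

    def dominant_loci(self) -> tuple[np.ndarray, np.ndarray]:
        """(d0, d1) of each mouse's expressed haplotype."""
        b = self.dom == 1
        return np.where(b, self.d0b, self.d0a), np.where(b, self.d1b, self.d1a)

    def dispersal_phenotype(self, i: int, density: float) -> float:
        """Propensity of mouse ``i`` to disperse at the given patch density,
        from the dominant haplotype's reaction norm, clamped to [0, 1]."""
        if self.dom[i] == 0:
            d0, d1 = self.d0a[i], self.d1a[i]
        else:
            d0, d1 = self.d0b[i], self.d1b[i]
        return float(kernels.phenotype_kernel(d0, d1, density))


@dataclass
class SimulationState:
    """One replicate's mutable state: the turn counter, the living mice and
    the current integer patch capacities. The RNG state is numba's global
    stream, fixed by the replicate seed (see :func:`kernels.seed_rng`)."""

    turn: int
    population: Population
    capacities: np.ndarray


def init_world(params: SimParams) -> np.ndarray:
    """Draw the S integer patch capacities from Normal(mean_k, sigma_k0),
    redrawn until inside ``mean_k +/- 2 sigma_k0``."""
    return kernels.init_capacities(params.n_patches, params.mean_k, params.sigma_k0)


def redraw_capacities(capacities: np.ndarray, params: SimParams) -> None:
    """Per-turn in-place capacity update (bounded random walk)."""
    kernels.redraw_capacities(capacities, params.mean_k, params.sigma_k0, params.sigma_kx)


def init_population(params: SimParams) -> Population:
    """The ``init_pop`` founders: age 1, all +/+, uniform d0 per haplotype."""
    return Population.from_arrays(
        kernels.init_population_kernel(params.init_pop, params.n_patches)
    )


def introduce_t(state: SimulationState) -> int:
    """Convert half of the living mice (rounded down) from +/+ to +/t.

    One uniformly chosen chromosome per converted mouse flips its allele to
    t with its dispersal loci untouched, and becomes dominant. Raises
    ``RuntimeError`` on an empty population (the run is extinct).
    """
    pop = state.population
    if len(pop) == 0:
        raise RuntimeError("cannot introduce t into an extinct population")
    return int(kernels.introduce_t_kernel(pop.allele_a, pop.allele_b, pop.dom))
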
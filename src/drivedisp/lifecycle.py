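"""Stage-by-stage wrappers over the compiled kernels.

:func:`run_turn` executes a complete turn (capacity redraw -> dispersal ->
mating -> birth -> mortality/aging). The individual stage functions expose
the same kernels one stage at a time for inspection and testing; both paths
share the compiled code in :mod:`drivedisp.kernels`, so there is a single
implementation of every rule. Seed :func:`drivedisp.kernels.seed_rng`
before calling any of these.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels, rules
from .params import SimParams
from .population import Population, SimulationState


@dataclass(frozen=True)
class MatingTable:
    """This turn's matings in CSR form: the mates of ``mothers[j]`` are
    ``mate_idx[indptr[j]:indptr[j+1]]`` (mouse indices, ordered as
    accepted)."""

    mothers: np.ndarray
    indptr: np.ndarray
    mate_idx: np.ndarray

    @property
    def n_mothers(self) -> int:
        return self.mothers.size

    def mate_counts(self) -> np.ndarray:
        return np.diff(self.indptr)

    def mates_of(self, j: int) -> np.ndarray:
        return self.mate_idx[self.indptr[j]:self.indptr[j + 1]]


def dispersal_step(state: SimulationState, params: SimParams) -> tuple[int, int]:
    """Dispersal of every age-1 mouse against the turn-start density
    snapshot; dispersers die with probability ``m_disp``, survivors move to
    a uniform other patch. Compacts the population in place and returns
    (number dispersing, number dying en route)."""
    pop = state.population
    density = pop.patch_counts(params.n_patches)
    alive = np.ones(len(pop), np.bool_)
    n_tried, n_died = kernels.dispersal_kernel(
        pop.age, pop.patch, pop.d0a, pop.d1a, pop.d0b, pop.d1b, pop.dom,
        alive, density, params.m_disp)
    if n_died:
        state.population = Population(*(a[alive] for a in pop.arrays()))
    return int(n_tried), int(n_died)


def mating_step(state: SimulationState, params: SimParams) -> MatingTable:
    """Mate every adult female on a patch with at least one adult male with
    ``1 + Binomial(m - 1, alpha)`` males drawn without replacement."""
    pop = state.population
    alive = np.ones(len(pop), np.bool_)
    mothers, indptr, mate_idx = kernels.mating_kernel(
        pop.sex, pop.age, pop.patch, alive, params.n_patches, params.alpha)
    return MatingTable(mothers, indptr, mate_idx)


def birth_step(state: SimulationState, table: MatingTable,
               params: SimParams, mut_rate: float | None = None) -> Population:
    """Produce and append this turn's newborns; returns them as their own
    :class:`Population` for inspection. ``mut_rate`` defaults to the
    schedule value at the current turn."""
    pop = state.population
    if mut_rate is None:
        mut_rate = rules.mutation_rate(state.turn, params)
    counts = pop.patch_counts(params.n_patches)
    born = kernels.birth_kernel(
        pop.sex, pop.patch, pop.allele_a, pop.allele_b,
        pop.d0a, pop.d1a, pop.d0b, pop.d1b,
        table.mothers, table.indptr, table.mate_idx, counts, state.capacities,
        params.c, params.p_drive, params.effective_tau, params.sterile_tt_males,
        mut_rate, params.mut_step_d0, params.mut_step_d1, params.two_locus,
        params.max_litter, params.litter_offset, params.litter_rate)
    newborns = Population(
        sex=born[0], age=np.zeros(born[0].size, np.int64), patch=born[1],
        allele_a=born[2], allele_b=born[3],
        d0a=born[4], d1a=born[5], d0b=born[6], d1b=born[7], dom=born[8])
    state.population = Population(*(
        np.concatenate([a, b]) for a, b in zip(pop.arrays(), newborns.arrays())
    ))
    return newborns


def mortality_step(state: SimulationState, params: SimParams) -> int:
    """Density-independent mortality (probability ``m_turn`` each), then
    uniform removal of the excess above each patch capacity; survivors age
    by one turn. Returns the number of deaths."""
    pop = state.population
    alive = np.ones(len(pop), np.bool_)
    kernels.mortality_kernel(pop.age, pop.patch, alive, state.capacities,
                             params.m_turn)
    n_dead = int((~alive).sum())
    if n_dead:
        state.population = Population(*(a[alive] for a in pop.arrays()))
    return n_dead


def run_turn(state: SimulationState, params: SimParams) -> SimulationState:
    """Execute one full turn via the fused kernel and advance the turn
    counter. The capacity array is updated in place."""
    pop = state.population
    mut_rate = rules.mutation_rate(state.turn, params)
    arrays = kernels.turn_kernel(
        *pop.arrays(), state.capacities,
        params.mean_k, params.sigma_k0, params.sigma_kx,
        params.alpha, params.m_disp, params.m_turn,
        params.c, params.p_drive, params.effective_tau, params.sterile_tt_males,
        mut_rate, params.mut_step_d0, params.mut_step_d1, params.two_locus,
        params.max_litter, params.litter_offset, params.litter_rate)
    state.population = Population.from_arrays(arrays)
    state.turn += 1
    return state
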
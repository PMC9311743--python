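"""Whole-replicate driver: run a seeded simulation and collect its outputs.

A replicate runs ``n_turns`` turns of the life cycle, introduces the t
haplotype into half of the population after the scheduled fraction of turns,
records a per-turn summary row, and — if driver and wildtype coexist to the
end — keeps every chromosome of the living mice over the final ten turns as
the evolved-phenotype sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels, rules
from .params import SimParams
from .population import Population, SimulationState, init_population, init_world, introduce_t

STATUS_RUNNING = "running"
STATUS_COMPLETED = "completed"
STATUS_T_EXTINCT = "t_extinct"
STATUS_PLUS_EXTINCT = "plus_extinct"
STATUS_POP_EXTINCT = "pop_extinct"

#: stable schema of the per-turn summary table
SUMMARY_COLUMNS = [
    "turn", "n_mice", "n_het", "n_tt", "freq_het",
    "mean_d0_plus", "mean_d1_plus", "mean_d0_t", "mean_d1_t", "status",
]

#: stable schema of the chromosome sample table (replicate/seed are added
#: by the output writer and the sweep layer)
SAMPLE_COLUMNS = ["turn", "allele", "d0", "d1"]


@dataclass
class RunResult:
    """Outcome of one replicate.

    ``summary`` holds one row per recorded turn; ``samples`` holds the
    last-ten-turn chromosome sample (``None`` unless the run completed with
    both chromosomes surviving). ``status`` is ``completed`` or one of the
    extinction statuses.
    """

    params: SimParams
    seed: int
    status: str
    turns_completed: int
    summary: pd.DataFrame
    samples: pd.DataFrame | None = None
    n_converted: int = 0

    @property
    def completed(self) -> bool:
        return self.status == STATUS_COMPLETED


def _summary_row(turn: int, pop: Population) -> tuple:
    n = len(pop)
    aa = pop.allele_a
    ab = pop.allele_b
    n_het = int((aa != ab).sum())
    n_tt = int(((aa == kernels.DRIVER) & (ab == kernels.DRIVER)).sum())
    plus_a = aa == kernels.WILDTYPE
    plus_b = ab == kernels.WILDTYPE
    n_plus = int(plus_a.sum() + plus_b.sum())
    n_t = 2 * n - n_plus
    if n_plus:
        d0_plus = (pop.d0a[plus_a].sum() + pop.d0b[plus_b].sum()) / n_plus
        d1_plus = (pop.d1a[plus_a].sum() + pop.d1b[plus_b].sum()) / n_plus
    else:
        d0_plus = d1_plus = np.nan
    if n_t:
        d0_t = (pop.d0a[~plus_a].sum() + pop.d0b[~plus_b].sum()) / n_t
        d1_t = (pop.d1a[~plus_a].sum() + pop.d1b[~plus_b].sum()) / n_t
    else:
        d0_t = d1_t = np.nan
    freq_het = n_het / n if n else np.nan
    return (turn, n, n_het, n_tt, freq_het, d0_plus, d1_plus, d0_t, d1_t)


def _chromosome_snapshot(turn: int, pop: Population):
    allele = np.concatenate([pop.allele_a, pop.allele_b])
    d0 = np.concatenate([pop.d0a, pop.d0b])
    d1 = np.concatenate([pop.d1a, pop.d1b])
    return (np.full(allele.size, turn, np.int64), allele, d0, d1)


def run_simulation(params: SimParams, seed: int | None = None,
                   record_every: int = 1, sample_last_turns: int = 10) -> RunResult:
    """Run one seeded replicate of ``params`` and return its results.

    ``record_every`` thins the per-turn summary (row ``turn`` is the index
    of the completed turn); the final turn of a run is always recorded.
    Runs terminate early, with the matching status, as soon as the t or the
    + chromosome class (from the introduction turn on) or the whole
    population hits zero.
    """
    if seed is None:
        seed = params.seed
    seed = int(seed)
    kernels.seed_rng(seed)
    capacities = init_world(params)
    state = SimulationState(turn=0, population=init_population(params),
                            capacities=capacities)
    t_intro = params.t_intro_turn
    n_turns = params.n_turns
    sample_from = n_turns - sample_last_turns

    rows: list[tuple] = []
    snapshots: list[tuple] = []
    status = STATUS_RUNNING
    n_converted = 0
    turn = -1
    for turn in range(n_turns):
        if turn == t_intro:
            if len(state.population) == 0:
                status = STATUS_POP_EXTINCT
                break
            n_converted = introduce_t(state)
        mut_rate = rules.mutation_rate(turn, params)
        arrays = kernels.turn_kernel(
            *state.population.arrays(), state.capacities,
            params.mean_k, params.sigma_k0, params.sigma_kx,
            params.alpha, params.m_disp, params.m_turn,
            params.c, params.p_drive, params.effective_tau,
            params.sterile_tt_males, mut_rate,
            params.mut_step_d0, params.mut_step_d1, params.two_locus,
            params.max_litter, params.litter_offset, params.litter_rate)
        pop = Population.from_arrays(arrays)
        state.population = pop
        state.turn = turn + 1

        record = (turn % record_every == 0) or turn == n_turns - 1
        if record:
            rows.append(_summary_row(turn, pop))
        if turn >= sample_from:
            snapshots.append(_chromosome_snapshot(turn, pop))

        if len(pop) == 0:
            status = STATUS_POP_EXTINCT
            if not record:
                rows.append(_summary_row(turn, pop))
            break
        if turn >= t_intro:
            n_plus, n_t = pop.chromosome_counts()
            if n_t == 0:
                status = STATUS_T_EXTINCT
            elif n_plus == 0:
                status = STATUS_PLUS_EXTINCT
            if status != STATUS_RUNNING:
                if not record:
                    rows.append(_summary_row(turn, pop))
                break
    if status == STATUS_RUNNING:
        status = STATUS_COMPLETED

    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS[:-1])
    summary["status"] = STATUS_RUNNING
    if len(summary):
        summary.iloc[-1, summary.columns.get_loc("status")] = status

    samples = None
    if status == STATUS_COMPLETED and snapshots:
        samples = pd.DataFrame({
            "turn": np.concatenate([s[0] for s in snapshots]),
            "allele": np.where(
                np.concatenate([s[1] for s in snapshots]) == kernels.DRIVER,
                "t", "+"),
            "d0": np.concatenate([s[2] for s in snapshots]),
            "d1": np.concatenate([s[3] for s in snapshots]),
        })

    return RunResult(params=params, seed=seed, status=status,
                     turns_completed=turn + 1, summary=summary,
                     samples=samples, n_converted=n_converted)
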
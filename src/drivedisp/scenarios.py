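"""Named study conditions, parameter grids and replicated sweeps.

The "natural condition" is the parameter set that mimics wild house-mouse
populations: moderate spatial and temporal carrying-capacity heterogeneity
(both SDs 15), remating acceptance alpha = 0.02, fully lethal t/t
(tau = 0), 90% drive and a 15% siring probability against a single wildtype
rival. The grids vary polyandry and homozygote viability, environmental
heterogeneity, and generalized driver traits around it.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .params import LocusMode, SimParams
from .simulate import RunResult, run_simulation

#: full-scale turn counts of the original study design
FULL_TURNS = {LocusMode.ONE_LOCUS: 100_000, LocusMode.TWO_LOCUS: 1_000_000}

#: desk-scale defaults used by the scaled-run mode
SCALED_TURNS = 20_000
SCALED_INIT_POP = 5_000

DEFAULT_REPLICATES_SINGLE = 10
DEFAULT_REPLICATES_GRID = 3


@dataclass(frozen=True)
class Condition:
    """A labelled parameter set plus its replicate count."""

    label: str
    params: SimParams
    n_replicates: int = DEFAULT_REPLICATES_SINGLE

    def scaled(self, n_turns: int = SCALED_TURNS,
               init_pop: int = SCALED_INIT_POP) -> "Condition":
        """Desk-scale copy: fewer turns and founders, with the introduction
        fraction and the 10%/90% mutation-schedule proportions preserved
        (they are defined as fractions of ``n_turns``)."""
        return replace(self, params=self.params.replace(
            n_turns=n_turns, init_pop=init_pop))


@dataclass
class SweepResult:
    """All replicates of one condition, with extinction bookkeeping."""

    condition: Condition
    results: list[RunResult] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def completed(self) -> list[RunResult]:
        return [r for r in self.results if r.completed]

    @property
    def status_counts(self) -> Counter:
        return Counter(r.status for r in self.results)

    @property
    def n_coexisting(self) -> int:
        return len(self.completed)


def natural_condition(locus_mode: LocusMode | str = LocusMode.ONE_LOCUS,
                      **overrides) -> Condition:
    """The natural condition at the requested locus mode, at the full-scale
    turn count for that mode (100,000 one-locus / 1,000,000 two-locus)
    unless overridden."""
    locus_mode = LocusMode(locus_mode)
    params = SimParams(locus_mode=locus_mode,
                       n_turns=FULL_TURNS[locus_mode]).replace(**overrides)
    return Condition(label=f"natural_{locus_mode.value}", params=params)


def grid_alpha_tau(locus_mode: LocusMode | str = LocusMode.ONE_LOCUS,
                   alphas=(0.0, 0.01, 0.02), taus=(0.0, 0.25, 0.5),
                   **overrides) -> list[Condition]:
    """Polyandry x homozygote-viability grid around the natural condition.

    The natural condition sits at the (alpha = 0.02, tau = 0) corner; the
    opposite corner (alpha = 0, tau = 0.5) removes both deleterious driver
    traits as far as the grid reaches.
    """
    base = natural_condition(locus_mode, **overrides)
    return [
        Condition(label=f"alpha={a:g},tau={t:g}",
                  params=base.params.replace(alpha=a, tau=t),
                  n_replicates=DEFAULT_REPLICATES_GRID)
        for a in alphas for t in taus
    ]


def grid_heterogeneity(sigmas=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0),
                       **overrides) -> list[Condition]:
    """All 36 combinations of spatial (sigma_k0) and temporal (sigma_kx)
    heterogeneity, otherwise the natural two-locus settings."""
    base = natural_condition(LocusMode.TWO_LOCUS, **overrides)
    return [
        Condition(label=f"sigma_k0={s0:g},sigma_kx={sx:g}",
                  params=base.params.replace(sigma_k0=s0, sigma_kx=sx),
                  n_replicates=DEFAULT_REPLICATES_GRID)
        for s0 in sigmas for sx in sigmas
    ]


def _increments(lo: float, hi: float, step: float = 0.05) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)


def grid_driver_traits(**overrides) -> tuple[list[Condition], list[Condition]]:
    """The two generalized-driver sweeps (one-locus, sigma 15/15).

    Sweep A: homozygote viability tau in 0.5..1 x drive strength p_drive in
    0.5..1, both in 0.05 increments, without polyandry (alpha = 0).
    Sweep B: sperm-competition disadvantage p_t_sperm in 0..0.5 x p_drive in
    0.5..1, with tau = 0 and alpha = 0.02.
    """
    base = natural_condition(LocusMode.ONE_LOCUS, **overrides)
    sweep_a = [
        Condition(label=f"tau={t:g},p_drive={d:g}",
                  params=base.params.replace(alpha=0.0, tau=t, p_drive=d),
                  n_replicates=DEFAULT_REPLICATES_GRID)
        for t in _increments(0.5, 1.0) for d in _increments(0.5, 1.0)
    ]
    sweep_b = [
        Condition(label=f"p_t_sperm={s:g},p_drive={d:g}",
                  params=base.params.replace(alpha=0.02, tau=0.0,
                                             p_t_sperm=s, p_drive=d),
                  n_replicates=DEFAULT_REPLICATES_GRID)
        for s in _increments(0.0, 0.5) for d in _increments(0.5, 1.0)
    ]
    return sweep_a, sweep_b


def replicate_seed(base_seed: int, condition_index: int, replicate_index: int) -> int:
    """Deterministic, counter-based per-replicate seed.

    Derived from ``(base_seed, condition_index, replicate_index)`` alone, so
    adding replicates or conditions never perturbs existing ones, and any
    replicate can be re-executed exactly from the sweep manifest.
    """
    ss = np.random.SeedSequence([int(base_seed), int(condition_index),
                                 int(replicate_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_condition(condition: Condition, base_seed: int,
                  condition_index: int = 0,
                  n_replicates: int | None = None,
                  record_every: int = 1) -> SweepResult:
    """Run all replicates of one condition sequentially (replicates share
    nothing but derived seeds, so results are order-independent)."""
    n_rep = n_replicates if n_replicates is not None else condition.n_replicates
    out = SweepResult(condition=condition)
    for r in range(n_rep):
        seed = replicate_seed(base_seed, condition_index, r)
        out.seeds.append(seed)
        out.results.append(run_simulation(condition.params, seed=seed,
                                          record_every=record_every))
    return out


def run_sweep(conditions: list[Condition], base_seed: int,
              n_replicates: int | None = None,
              record_every: int = 1) -> list[SweepResult]:
    """Run every condition of a sweep; per-replicate seeds are derived from
    ``base_seed`` and the (condition, replicate) counters."""
    return [
        run_condition(cond, base_seed, condition_index=i,
                      n_replicates=n_replicates, record_every=record_every)
        for i, cond in enumerate(conditions)
    ]
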
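"""Closed-form model rules, shared by the simulator and the analysis layer.

These are the deterministic formulas of the model; their stochastic
counterparts live in :mod:`drivedisp.kernels` (a property test asserts the
two agree).
"""
from __future__ import annotations

import numpy as np

from .params import SimParams

_DEFAULTS = SimParams()


def reaction_norm(d0, d1, density):
    """Dispersal propensity of a (D0, D1) reaction norm at a density.

    Linear in density, clamped to the probability range [0, 1]. This is the
    single definition of "dispersal propensity" used both for the
    simulator's dispersal decision and for the evolved-phenotype analysis.
    Accepts scalars or arrays.
    """
    return np.clip(np.asarray(d0) + np.asarray(d1) * np.asarray(density), 0.0, 1.0)


def litter_size(n_patch: int, capacity: int, params: SimParams | None = None) -> int:
    """Offspring count at the start of a pregnancy on a patch with
    ``n_patch`` occupants and carrying capacity ``capacity``.

    ``round(max_litter / (1 + exp(litter_rate * (litter_offset + Np - Kp))))``:
    zero at capacity, exactly one at one below capacity, saturating at
    ``max_litter`` on an empty patch.
    """
    p = params or _DEFAULTS
    with np.errstate(over="ignore"):
        v = p.max_litter / (1.0 + np.exp(p.litter_rate * (p.litter_offset + n_patch - capacity)))
    return int(np.floor(v + 0.5))


def sire_probabilities(mate_genotypes, params: SimParams | None = None) -> np.ndarray:
    """Per-mate siring probability for one offspring of a multiply mated female.

    ``mate_genotypes`` counts t alleles per mate (0 = +/+, 1 = +/t, 2 = t/t).
    Each t-carrying mate sires with probability ``c / (c*Nt + N++)`` and each
    +/+ mate with ``1 / (c*Nt + N++)``, where ``c`` is the sperm-competitive
    weight of t-carriers. In the sterile-male variant t/t males are removed
    from the pool before counting. If every fertile mate is a t-carrier of
    weight zero, the c -> 0 limit (uniform among them) applies; an empty
    fertile pool yields all-zero probabilities (no sire).
    """
    p = params or _DEFAULTS
    g = np.asarray(mate_genotypes, dtype=np.int64)
    fertile = np.ones(g.size, dtype=bool)
    if p.sterile_tt_males:
        fertile &= g != 2
    weights = np.where(g >= 1, p.c, 1.0) * fertile
    total = weights.sum()
    if total > 0:
        return weights / total
    n_t = int((fertile & (g >= 1)).sum())
    if n_t > 0:
        return np.where(fertile & (g >= 1), 1.0 / n_t, 0.0)
    return np.zeros(g.size)


def mutation_rate(turn: int, params: SimParams | None = None) -> float:
    """Per-locus mutation probability at a given turn.

    Piecewise linear: ``mut_rate_max`` at turn 0 falling to ``mut_rate_min``
    at the t-introduction turn (10% of the run by default), resetting to
    ``mut_rate_max`` at the introduction turn and falling again to
    ``mut_rate_min`` at the final turn. The early burst lets the wildtype
    find its optimum before the driver enters; the second burst gives both
    chromosomes mutational input while they compete.
    """
    p = params or _DEFAULTS
    if not 0 <= turn <= p.n_turns:
        raise ValueError(f"turn must be in [0, {p.n_turns}], got {turn}")
    t_intro = p.t_intro_turn
    if turn < t_intro:
        frac = turn / t_intro
    elif p.n_turns == t_intro:
        frac = 1.0
    else:
        frac = (turn - t_intro) / (p.n_turns - t_intro)
    return p.mut_rate_max + (p.mut_rate_min - p.mut_rate_max) * frac


def expected_mates(n_males: int, alpha: float) -> float:
    """Mean number of mates of a female on a patch with ``n_males`` adult
    males: ``1 + alpha * (n_males - 1)``."""
    return 1.0 + alpha * (n_males - 1)


def single_mating_probability(n_males: int, alpha: float) -> float:
    """Probability that such a female mates only once: ``(1-alpha)**(n-1)``."""
    return (1.0 - alpha) ** (n_males - 1)
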
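"""Global simulation parameters.

A :class:`SimParams` instance holds every global of the model: world geometry
and carrying-capacity heterogeneity, the driver's transmission and fitness
traits, the mating and mortality rates, the mutation schedule of the dispersal
loci, and run control (turns, founders, seed). Defaults correspond to the
"natural condition" of the t haplotype: moderate spatial and temporal
heterogeneity (both SDs 15), rare remating acceptance (alpha = 0.02), fully
lethal t/t homozygotes (tau = 0), 90% drive, and a 15% siring probability for
a t-carrying male against a single wildtype rival.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Any


class LocusMode(str, Enum):
    """Number of evolving dispersal loci per chromosome.

    ``ONE_LOCUS`` evolves only the density-independent propensity D0;
    ``TWO_LOCUS`` additionally evolves D1, the slope of propensity on local
    density, so reaction norms can become density dependent.
    """

    ONE_LOCUS = "one_locus"
    TWO_LOCUS = "two_locus"


#: fields that must lie in the closed unit interval
_UNIT_INTERVAL = (
    "alpha",
    "tau",
    "p_t_sperm",
    "m_disp",
    "m_turn",
    "mut_rate_max",
    "mut_rate_min",
    "t_intro_turn_fraction",
)

_NON_NEGATIVE = ("sigma_k0", "sigma_kx", "mut_step_d0", "mut_step_d1")


@dataclass(frozen=True)
class SimParams:
    """All global parameters of one simulation run.

    Parameters
    ----------
    n_patches:
        Number of island habitat patches S.
    mean_k:
        Mean carrying capacity mu of the patches.
    sigma_k0:
        SD of the initial capacity draw; also sets the hard capacity bounds
        ``mean_k +/- 2 sigma_k0`` (spatial heterogeneity).
    sigma_kx:
        SD of the per-turn capacity redraw around the current value
        (temporal heterogeneity; creates temporal autocorrelation).
    alpha:
        Probability that an already-mated female accepts each further
        approaching male (polyandry rate).
    tau:
        Viability of a t/t embryo.
    p_drive:
        Probability that a heterozygous male transmits the t chromosome.
    p_t_sperm:
        Siring probability of a t-carrying male competing against one
        wildtype male; converted internally to the competitive weight
        ``c = p_t_sperm / (1 - p_t_sperm)``.
    m_disp:
        Probability that dispersal kills the disperser.
    m_turn:
        Density-independent per-turn mortality.
    n_turns:
        Number of turns (generatios of the life cycle) to simulate.
    t_intro_turn_fraction:
        Fraction of ``n_turns`` after which half of all mice are converted
        from +/+ to +/t.
    init_pop:
        Number of founder mice (age 1, all +/+).
    locus_mode:
        One- or two-locus dispersal genetics, see :class:`LocusMode`.
    sterile_tt_males:
        If true, t/t is fully viable but t/t males never sire offspring
        (they still occupy matings).
    max_litter, litter_offset, litter_rate:
        Parameters of the logistic litter-size rule
        ``round(max_litter / (1 + exp(litter_rate * (litter_offset + Np - Kp))))``.
    mut_rate_max, mut_rate_min:
        Endpoints of the piecewise-linear per-locus mutation schedule.
    mut_step_d0, mut_step_d1:
        Mutation step sizes of the intercept and slope loci.
    seed:
        Default RNG seed of the replicate.
    """

    n_patches: int = 49
    mean_k: float = 50.0
    sigma_k0: float = 15.0
    sigma_kx: float = 15.0
    alpha: float = 0.02
    tau: float = 0.0
    p_drive: float = 0.9
    p_t_sperm: float = 0.15
    m_disp: float = 0.3
    m_turn: float = 0.25
    n_turns: int = 100_000
    t_intro_turn_fraction: float = 0.1
    init_pop: int = 5_000
    locus_mode: LocusMode = LocusMode.ONE_LOCUS
    sterile_tt_males: bool = False
    max_litter: int = 6
    litter_offset: float = 24.0
    litter_rate: float = 0.1
    mut_rate_max: float = 1.0
    mut_rate_min: float = 1e-3
    mut_step_d0: float = 1e-3
    mut_step_d1: float = 2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "locus_mode", LocusMode(self.locus_mode))
        for name in _UNIT_INTERVAL:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in _NON_NEGATIVE:
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if not 0.5 <= self.p_drive <= 1.0:
            raise ValueError(f"p_drive must be in [0.5, 1], got {self.p_drive!r}")
        if self.p_t_sperm >= 1.0:
            raise ValueError("p_t_sperm must be < 1 so the competitive weight c is finite")
        if self.n_patches < 2:
            raise ValueError(f"n_patches must be >= 2, got {self.n_patches!r}")
        if self.mean_k <= 0:
            raise ValueError(f"mean_k must be > 0, got {self.mean_k!r}")
        if self.n_turns < 1:
            raise ValueError(f"n_turns must be >= 1, got {self.n_turns!r}")
        if self.init_pop < 1:
            raise ValueError(f"init_pop must be >= 1, got {self.init_pop!r}")
        if self.max_litter < 0:
            raise ValueError(f"max_litter must be >= 0, got {self.max_litter!r}")
        if not 0 <= int(self.seed) < 2**31:
            raise ValueError(f"seed must be in [0, 2**31), got {self.seed!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def c(self) -> float:
        """Sperm-competitive weight of a t-carrying male relative to +/+."""
        return self.p_t_sperm / (1.0 - self.p_t_sperm)

    @property
    def t_intro_turn(self) -> int:
        """Turn at which half of the population is converted to +/t."""
        return int(round(self.t_intro_turn_fraction * self.n_turns))

    @property
    def two_locus(self) -> bool:
        return self.locus_mode is LocusMode.TWO_LOCUS

    @property
    def effective_tau(self) -> float:
        """t/t embryo viability actually applied at birth.

        The sterile-male variant models t/t as fully viable but infertile as
        males, so it overrides ``tau`` with 1.
        """
        return 1.0 if self.sterile_tt_males else self.tau

    # -- plumbing -----------------------------------------------------------

    def replace(self, **changes: Any) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["locus_mode"] = self.locus_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(self))
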
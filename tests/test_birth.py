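"""The birth machinery: litter sizes, sire assignment under sperm
competition, drive-biased transmission, and the mutation model."""
import numpy as np
import pytest
from scipy.special import expit

from drivedisp import SimParams, litter_size, mutation_rate, sire_probabilities
from drivedisp import kernels
from drivedisp.lifecycle import MatingTable, birth_step
from drivedisp.population import Population


def _merge(*pops):
    return Population(*(np.concatenate(parts) for parts in
                        zip(*(p.arrays() for p in pops))))


# -- litter size -------------------------------------------------------------

@pytest.mark.parametrize("n_patch, capacity, expected", [
    (50, 50, 0),     # at capacity: no offspring
    (49, 50, 1),     # one below capacity: exactly one
    (0, 50, 6),      # empty patch: full litter
    (80, 50, 0),     # far above capacity: monotone to zero
    (119, 120, 1),
])
def test_litter_size_examples(n_patch, capacity, expected):
    assert litter_size(n_patch, capacity) == expected


def test_litter_size_matches_logistic_oracle_on_grid():
    """round(6 / (1 + exp(0.1 (24 + Np - Kp)))) for every
    (Np, Kp) in [0, 120]^2, against an independent expit evaluation."""
    for n_patch in range(121):
        for capacity in range(121):
            oracle = round(6.0 * expit(-0.1 * (24.0 + n_patch - capacity)))
            assert litter_size(n_patch, capacity) == oracle


# -- sire assignment ---------------------------------------------------------

def test_sire_probability_one_het_vs_one_wildtype_is_default_p_t_sperm():
    probs = sire_probabilities([1, 0])
    assert probs[0] == pytest.approx(0.15)
    assert probs.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("genotypes, expected", [
    ([0], [1.0]),                      # single +/+ mate sires for sure
    ([1, 1], [0.5, 0.5]),              # two t-carriers split evenly
    ([2, 0], None),                    # computed below for default c
])
def test_sire_probability_structure(genotypes, expected):
    probs = sire_probabilities(genotypes)
    if expected is None:
        c = SimParams().c
        expected = [c / (c + 1), 1 / (c + 1)]
    assert probs == pytest.approx(expected)


def test_sterile_tt_males_are_ignored_as_sires():
    params = SimParams(sterile_tt_males=True)
    probs = sire_probabilities([2, 0], params)
    assert probs == pytest.approx([0.0, 1.0])
    assert sire_probabilities([2, 2], params).sum() == 0.0


def test_zero_sperm_weight_limit_is_uniform_among_t_mates():
    params = SimParams(p_t_sperm=0.0)
    assert sire_probabilities([1, 1], params) == pytest.approx([0.5, 0.5])
    assert sire_probabilities([1, 0], params) == pytest.approx([0.0, 1.0])


def _birth(mothers_pop, males_pop, mates_per_mother, params, mut_rate=0.0,
           capacity=None):
    """Run one birth step for many identical mothers sharing a mate list.

    Default capacity leaves the patch far below carrying capacity so every
    mother conceives a full litter."""
    pop = _merge(males_pop, mothers_pop)
    if capacity is None:
        capacity = len(pop) + 100
    n_m = len(males_pop)
    n_f = len(mothers_pop)
    mothers = np.arange(n_m, n_m + n_f, dtype=np.int64)
    k = len(mates_per_mother)
    table = MatingTable(
        mothers=mothers,
        indptr=np.arange(0, (n_f + 1) * k, k, dtype=np.int64),
        mate_idx=np.tile(np.asarray(mates_per_mother, np.int64), n_f),
    )
    from drivedisp.population import SimulationState
    state = SimulationState(turn=0, population=pop,
                            capacities=np.array([capacity, capacity], np.int64))
    return birth_step(state, table, params, mut_rate=mut_rate)


def test_empirical_sire_frequencies_match_weighted_competition(make_population):
    """Nt = 2 t-carrying and N++ = 3 wildtype mates at c = 3/17: each
    t-carrier sires c/(2c+3) = 1/19 and each +/+ 17/57 of ~1.2e5 offspring,
    within 3 binomial SE. Sires are identified by their private d0 values
    (no recombination, mutation off)."""
    ids = np.arange(5) / 10.0 + 0.1
    males = make_population(5, sex=0, allele_a=[1, 1, 0, 0, 0],
                            d0a=ids, d0b=ids)
    mothers = make_population(20_000, sex=1)
    params = SimParams(p_t_sperm=0.15, tau=1.0, n_patches=2)
    born = _birth(mothers, males, [0, 1, 2, 3, 4], params)
    n = len(born)
    assert n == 20_000 * 6
    c = params.c
    for m, p_exp in zip(range(5), [c / (2 * c + 3)] * 2 + [1 / (2 * c + 3)] * 3):
        frac = (born.d0a == ids[m]).mean()
        assert abs(frac - p_exp) < 3 * np.sqrt(p_exp * (1 - p_exp) / n)


def test_transmission_bias_of_heterozygous_sire(make_population):
    """A +/t sire transmits t with probability p_drive = 0.9; the mother's
    two chromosomes are transmitted 50:50 (1e5+ offspring, 3 binomial SE)."""
    male = make_population(1, sex=0, allele_a=1, d0a=0.9, d0b=0.1)
    mothers = make_population(17_000, sex=1, d0a=0.3, d0b=0.7)
    params = SimParams(tau=1.0, n_patches=2)
    born = _birth(mothers, male, [0], params)
    n = len(born)
    assert n == 17_000 * 6
    t_frac = (born.allele_a == 1).mean()
    assert abs(t_frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)
    mat_frac = (born.d0b == 0.3).mean()
    assert abs(mat_frac - 0.5) < 3 * np.sqrt(0.25 / n)
    # no recombination: the paternal haplotype is one of the sire's two
    assert set(np.unique(born.d0a)) <= {0.9, 0.1}
    # and every +/t newborn expresses the t haplotype
    het = born.genotypes() == 1
    t_on_a = born.allele_a[het] == 1
    assert np.array_equal(born.dom[het] == 0, t_on_a)


def test_fair_transmission_limit(make_population):
    male = make_population(1, sex=0, allele_a=1, d0a=0.9, d0b=0.1)
    mothers = make_population(17_000, sex=1)
    params = SimParams(p_drive=0.5, tau=1.0, n_patches=2)
    born = _birth(mothers, male, [0], params)
    t_frac = (born.allele_a == 1).mean()
    assert abs(t_frac - 0.5) < 3 * np.sqrt(0.25 / len(born))


def test_lethal_homozygotes_never_born(make_population):
    male = make_population(1, sex=0, allele_a=1, allele_b=1)
    mothers = make_population(5_000, sex=1, allele_a=1)
    params = SimParams(tau=0.0, n_patches=2)
    born = _birth(mothers, male, [0], params)
    assert np.all(born.genotypes() != 2)
    # t x +/t: half of conceptions are t/t and die, so ~3/6 born per litter
    assert len(born) == pytest.approx(5_000 * 3, rel=0.05)


def test_mother_at_capacity_has_no_offspring(make_population):
    male = make_population(1, sex=0)
    mothers = make_population(100, sex=1)
    params = SimParams(n_patches=2)
    born = _birth(mothers, male, [0], params, capacity=101)
    assert len(born) == 0


def test_sterile_scenario_single_tt_mate_yields_no_offspring(make_population):
    male = make_population(1, sex=0, allele_a=1, allele_b=1)
    mothers = make_population(200, sex=1)
    params = SimParams(sterile_tt_males=True, n_patches=2)
    born = _birth(mothers, male, [0], params)
    assert len(born) == 0


# -- mutation ----------------------------------------------------------------

def test_mutation_rate_schedule_endpoints_and_reset():
    params = SimParams(n_turns=10_000)
    t_intro = params.t_intro_turn
    assert mutation_rate(0, params) == 1.0
    assert mutation_rate(t_intro - 1, params) == pytest.approx(1e-3, abs=1.1e-3)
    # the rate snaps back to the maximum as the driver enters
    assert mutation_rate(t_intro, params) == 1.0
    assert mutation_rate(params.n_turns, params) == pytest.approx(1e-3)
    # midpoint of the second ramp
    mid = int(0.55 * params.n_turns)
    assert mutation_rate(mid, params) == pytest.approx((1.0 + 1e-3) / 2)
    with pytest.raises(ValueError):
        mutation_rate(params.n_turns + 1, params)


def test_mutation_steps_are_exact_and_boundary_clamped():
    hits = {0.1 + 1e-3: 0, 0.1 - 1e-3: 0}
    for _ in range(200):
        new = kernels.mutate_locus(0.1, 1.0, 1e-3, 0.0, 1.0)
        hits[new] += 1
    assert min(hits.values()) > 0  # both directions occur

    for _ in range(200):
        assert kernels.mutate_locus(0.0, 1.0, 1e-3, 0.0, 1.0) in (0.0, 1e-3)
        assert kernels.mutate_locus(1.0, 1.0, 1e-3, 0.0, 1.0) in (1.0, 1.0 - 1e-3)

    d1 = kernels.mutate_locus(0.5, 1.0, 2e-5, -1.0, 1.0)
    assert abs(d1 - 0.5) == pytest.approx(2e-5)

    assert kernels.mutate_locus(0.3, 0.0, 1e-3, 0.0, 1.0) == 0.3  # rate 0


def test_one_locus_mode_keeps_slope_frozen(make_population):
    male = make_population(1, sex=0)
    mothers = make_population(2_000, sex=1)
    params = SimParams(locus_mode="one_locus", n_patches=2)
    born = _birth(mothers, male, [0], params, mut_rate=1.0)
    assert np.all(born.d1a == 0.0) and np.all(born.d1b == 0.0)
    # while d0 always moved by one exact step
    assert np.all(np.isin(np.round(np.abs(born.d0a - 0.5), 12), [1e-3]))
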
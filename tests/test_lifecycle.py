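"""Stage-level behaviour: dispersal, mating, mortality and full turns."""
import numpy as np
import pytest

from drivedisp import SimParams
from drivedisp.lifecycle import (dispersal_step, mating_step, mortality_step,
                                 run_turn)
from drivedisp.rules import expected_mates, single_mating_probability


def _params(**kw):
    base = dict(n_patches=2, init_pop=10, n_turns=100)
    base.update(kw)
    return SimParams(**base)


# -- dispersal ---------------------------------------------------------------

def test_only_age_one_mice_disperse(make_population, make_state):
    pop = make_population(200, age=2, d0a=1.0, d0b=1.0)
    state = make_state(pop, capacities=[500, 500])
    n_tried, n_died = dispersal_step(state, _params(m_disp=0.0))
    assert (n_tried, n_died) == (0, 0)
    assert np.all(state.population.patch == 0)


def test_dispersal_mortality_rate(make_population, make_state):
    """10^4 mice with propensity 1 lose about the dispersal-mortality
    fraction (0.3) en route, within 3 binomial SE."""
    n = 10_000
    pop = make_population(n, age=1, d0a=1.0, d0b=1.0)
    state = make_state(pop, capacities=[n, n])
    n_tried, n_died = dispersal_step(state, _params(m_disp=0.3))
    assert n_tried == n
    assert abs(n_died / n - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)
    assert len(state.population) == n - n_died
    # survivors all left their natal patch (global dispersal, n_patches=2)
    assert np.all(state.population.patch == 1)


def test_zero_propensity_is_a_no_op(make_population, make_state):
    pop = make_population(500, age=1, d0a=0.0, d0b=0.0)
    state = make_state(pop, capacities=[600, 600])
    assert dispersal_step(state, _params(m_disp=0.3)) == (0, 0)
    assert np.all(state.population.patch == 0)


def test_dispersal_destination_uniform_over_other_patches(make_population, make_state):
    n, s = 10_000, 5
    pop = make_population(n, age=1, patch=2, d0a=1.0, d0b=1.0)
    state = make_state(pop, capacities=[n] * s)
    dispersal_step(state, _params(n_patches=s, m_disp=0.0))
    counts = np.bincount(state.population.patch, minlength=s)
    assert counts[2] == 0
    # each of the other four patches receives ~n/4
    se = np.sqrt(n * 0.25 * 0.75)
    assert np.all(np.abs(counts[[0, 1, 3, 4]] - n / 4) < 4 * se)


# -- mating ------------------------------------------------------------------

def test_monandry_without_remating_acceptance(make_population, make_state):
    males = make_population(26, sex=0)
    females = make_population(1_000, sex=1)
    pop = males.copy()
    merged = type(pop)(*(np.concatenate([a, b]) for a, b in
                         zip(males.arrays(), females.arrays())))
    state = make_state(merged, capacities=[2000, 2000])
    table = mating_step(state, _params(alpha=0.0))
    assert table.n_mothers == 1_000
    assert np.all(table.mate_counts() == 1)


def test_polyandrous_mate_count_and_single_mating_probability(
        make_population, make_state):
    """With alpha = 0.02 and 26 males, mean mates ~ 1 + 0.02*25 = 1.5 and
    the single-mating probability ~ 0.98^25, each within 3 SE (1e5 females)."""
    n_f, n_m, alpha = 100_000, 26, 0.02
    males = make_population(n_m, sex=0)
    females = make_population(n_f, sex=1)
    merged = type(males)(*(np.concatenate([a, b]) for a, b in
                           zip(males.arrays(), females.arrays())))
    state = make_state(merged, capacities=[n_f, n_f])
    table = mating_step(state, _params(alpha=alpha))
    k = table.mate_counts()

    mean_expected = expected_mates(n_m, alpha)
    se_mean = np.sqrt((n_m - 1) * alpha * (1 - alpha) / n_f)
    assert abs(k.mean() - mean_expected) < 3 * se_mean

    p1 = single_mating_probability(n_m, alpha)
    se_p1 = np.sqrt(p1 * (1 - p1) / n_f)
    assert abs((k == 1).mean() - p1) < 3 * se_p1

    # mates are distinct males from the female's own patch
    j = int(np.argmax(k))
    mates = table.mates_of(j)
    assert len(set(mates.tolist())) == len(mates)
    assert np.all(mates < n_m)


def test_females_without_local_males_do_not_mate(make_population, make_state):
    females = make_population(50, sex=1, patch=0)
    males = make_population(5, sex=0, patch=1)
    merged = type(males)(*(np.concatenate([a, b]) for a, b in
                           zip(females.arrays(), males.arrays())))
    state = make_state(merged, capacities=[100, 100])
    table = mating_step(state, _params(alpha=0.02))
    assert table.n_mothers == 0


# -- mortality ---------------------------------------------------------------

def test_turn_mortality_rate(make_population, make_state):
    n = 100_000
    pop = make_population(n)
    state = make_state(pop, capacities=[2 * n, 2 * n])
    dead = mortality_step(state, _params(m_turn=0.25))
    assert abs(dead / n - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


def test_capacity_truncation_leaves_no_overcrowded_patch(make_population, make_state):
    pop = make_population(3_000, patch=np.repeat([0, 1], [2_000, 1_000]))
    state = make_state(pop, capacities=[500, 1_500])
    mortality_step(state, _params(m_turn=0.0))
    counts = state.population.patch_counts(2)
    assert counts[0] == 500      # exactly the excess removed
    assert counts[1] == 1_000    # patches under capacity untouched


def test_zero_mortality_under_capacity_only_ages(make_population, make_state):
    pop = make_population(100, age=3)
    state = make_state(pop, capacities=[200, 200])
    dead = mortality_step(state, _params(m_turn=0.0))
    assert dead == 0
    assert np.all(state.population.age == 4)


# -- full turns --------------------------------------------------------------

def test_static_turn_leaves_composition_invariant(make_population, make_state):
    """With zero mortality, zero propensity, patches exactly at capacity
    (hence zero litters) and a frozen world, a turn changes nothing but
    ages."""
    pop = make_population(6, sex=np.tile([0, 1], 3), patch=np.repeat([0, 1], 3),
                          d0a=0.0, d0b=0.0)
    params = _params(sigma_kx=0.0, m_turn=0.0, m_disp=0.0, alpha=0.0)
    state = make_state(pop, capacities=[3, 3])
    before = {name: arr.copy() for name, arr
              in zip(("sex", "patch", "age"), (pop.sex, pop.patch, pop.age))}
    run_turn(state, params)
    after = state.population
    assert len(after) == 6
    assert np.array_equal(np.sort(after.patch), np.sort(before["patch"]))
    assert np.array_equal(np.sort(after.sex), np.sort(before["sex"]))
    assert np.array_equal(np.sort(after.age), np.sort(before["age"] + 1))


def test_turn_respects_capacity_feasibility(make_population, make_state):
    pop = make_population(2_000, sex=np.tile([0, 1], 1_000),
                          patch=np.arange(2_000) % 4)
    params = _params(n_patches=4, sigma_kx=0.0)
    state = make_state(pop, capacities=[40, 50, 60, 70])
    for _ in range(5):
        run_turn(state, params)
        counts = state.population.patch_counts(4)
        assert np.all(counts <= state.capacities)
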
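"""Numba-compiled inner loops of the life cycle.

The population lives in flat struct-of-arrays form (one entry per mouse);
every stage of a turn (capacity redraw, dispersal, mating, birth,
mortality/aging) is a compiled kernel, and :func:`turn_kernel` chains them
into one full turn. All randomness flows through numba's global legacy
``np.random`` state: call :func:`seed_rng` once per replicate before any
kernel and run replicates sequentially, and a seed fixes the whole
trajectory bit for bit (the kernels are deliberately single-threaded).

Conventions: ``sex`` 0 = male / 1 = female; alleles ``WILDTYPE`` (+) and
``DRIVER`` (t); each mouse carries haplotypes *a* and *b* with loci
``d0`` (propensity intercept) and ``d1`` (propensity slope on density);
``dom`` (0 = a, 1 = b) names the haplotype whose loci are expressed.
"""
from __future__ import annotations

import numpy as np
from numba import njit

WILDTYPE = 0
DRIVER = 1


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG stream (call once per replicate)."""
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# World: bounded, temporally autocorrelated carrying capacities
# ---------------------------------------------------------------------------

@njit(cache=True)
def draw_capacity(mean, sd, lo, hi):
    """One integer capacity: Normal(mean, sd) redrawn until inside [lo, hi]."""
    if sd <= 0.0:
        return int(np.floor(mean + 0.5))
    x = np.random.normal(mean, sd)
    while x < lo or x > hi:
        x = np.random.normal(mean, sd)
    return int(np.floor(x + 0.5))


@njit(cache=True)
def init_capacities(n_patches, mean_k, sigma_k0):
    lo = mean_k - 2.0 * sigma_k0
    hi = mean_k + 2.0 * sigma_k0
    caps = np.empty(n_patches, np.int64)
    for p in range(n_patches):
        caps[p] = draw_capacity(mean_k, sigma_k0, lo, hi)
    return caps


@njit(cache=True)
def redraw_capacities(caps, mean_k, sigma_k0, sigma_kx):
    """Per-turn capacity update: Normal(current, sigma_kx) within the
    sigma_k0 bounds. A degenerate world (either SD zero) keeps capacities
    fixed: with sigma_kx = 0 the draw is the current value, and with
    sigma_k0 = 0 the bound collapses to {mean_k}."""
    if sigma_kx <= 0.0 or sigma_k0 <= 0.0:
        return
    lo = mean_k - 2.0 * sigma_k0
    hi = mean_k + 2.0 * sigma_k0
    for p in range(caps.size):
        caps[p] = draw_capacity(float(caps[p]), sigma_kx, lo, hi)


# ---------------------------------------------------------------------------
# Elemental rules shared by the stages
# ---------------------------------------------------------------------------

@njit(cache=True)
def phenotype_kernel(d0, d1, density):
    """Dispersal propensity of a reaction norm at a density, clamped to [0, 1]."""
    p = d0 + d1 * density
    if p < 0.0:
        return 0.0
    if p > 1.0:
        return 1.0
    return p


@njit(cache=True)
def litter_size_kernel(n_patch, capacity, max_litter, offset, rate):
    """Logistic litter-size rule: 0 at capacity, 1 one below it, up to
    ``max_litter`` on an empty patch."""
    v = max_litter / (1.0 + np.exp(rate * (offset + n_patch - capacity)))
    return int(np.floor(v + 0.5))


@njit(cache=True)
def choose_transmitted(allele_a, allele_b, p_drive, apply_drive):
    """Index (0 = a, 1 = b) of the chromosome a parent passes on.

    Drive only distorts transmission in heterozygous males
    (``apply_drive`` true): the t chromosome wins with probability
    ``p_drive``. Everyone else transmits a fair coin flip.
    """
    if apply_drive and allele_a + allele_b == 1:
        transmit_t = np.random.random() < p_drive
        if (allele_a == DRIVER) == transmit_t:
            return 0
        return 1
    if np.random.random() < 0.5:
        return 0
    return 1


@njit(cache=True)
def mutate_locus(value, rate, step, lo, hi):
    """Mutate one locus with probability ``rate``: +/- ``step`` (fair
    direction), clamped to [lo, hi]."""
    if rate > 0.0 and np.random.random() < rate:
        if np.random.random() < 0.5:
            value += step
        else:
            value -= step
        if value < lo:
            value = lo
        elif value > hi:
            value = hi
    return value


# ---------------------------------------------------------------------------
# Stage kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def dispersal_kernel(age, patch, d0a, d1a, d0b, d1b, dom, alive, density,
                     m_disp):
    """Dispersal of every age-1 mouse against the turn-start density snapshot.

    A mouse whose uniform draw falls below its dominant haplotype's
    propensity disperses: it dies with probability ``m_disp``, otherwise it
    relocates to a uniformly chosen patch other than its origin (dispersal
    is global). Returns (number dispersing, number dying en route).
    """
    n_patches = density.size
    n_tried = 0
    n_died = 0
    for i in range(age.size):
        if not alive[i] or age[i] != 1:
            continue
        if dom[i] == 0:
            p = phenotype_kernel(d0a[i], d1a[i], density[patch[i]])
        else:
            p = phenotype_kernel(d0b[i], d1b[i], density[patch[i]])
        if np.random.random() < p:
            n_tried += 1
            if np.random.random() < m_disp:
                alive[i] = False
                n_died += 1
            else:
                dest = np.random.randint(0, n_patches - 1)
                if dest >= patch[i]:
                    dest += 1
                patch[i] = dest
    return n_tried, n_died


@njit(cache=True)
def mating_kernel(sex, age, patch, alive, n_patches, alpha):
    """Pair every adult female with her mates for this turn.

    On a patch with m adult males a female mates with ``1 + Binomial(m-1,
    alpha)`` of them (the first approacher is always accepted, each further
    one with probability alpha); because each female sees the males in a
    fresh random order, the mate set given its size is a uniform subset,
    which is how it is sampled here (partial Fisher-Yates). Males are not
    limited in their number of matings.

    Returns CSR-style arrays ``(mothers, indptr, mate_idx)``: female ``j``'s
    mates are ``mate_idx[indptr[j]:indptr[j+1]]``.
    """
    n = sex.size
    male_count = np.zeros(n_patches, np.int64)
    for i in range(n):
        if alive[i] and sex[i] == 0 and age[i] >= 1:
            male_count[patch[i]] += 1
    male_start = np.zeros(n_patches + 1, np.int64)
    for p in range(n_patches):
        male_start[p + 1] = male_start[p] + male_count[p]
    males = np.empty(male_start[n_patches], np.int64)
    fill = male_start[:n_patches].copy()
    for i in range(n):
        if alive[i] and sex[i] == 0 and age[i] >= 1:
            pp = patch[i]
            males[fill[pp]] = i
            fill[pp] += 1

    mothers = np.empty(n, np.int64)
    nf = 0
    for i in range(n):
        if alive[i] and sex[i] == 1 and age[i] >= 1 and male_count[patch[i]] > 0:
            mothers[nf] = i
            nf += 1
    mothers = mothers[:nf]
    np.random.shuffle(mothers)

    kcounts = np.empty(nf, np.int64)
    total = 0
    for j in range(nf):
        m = male_count[patch[mothers[j]]]
        k = 1
        if m > 1 and alpha > 0.0:
            k += np.random.binomial(m - 1, alpha)
        kcounts[j] = k
        total += k
    indptr = np.zeros(nf + 1, np.int64)
    for j in range(nf):
        indptr[j + 1] = indptr[j] + kcounts[j]
    mate_idx = np.empty(total, np.int64)
    for j in range(nf):
        p = patch[mothers[j]]
        s = male_start[p]
        m = male_count[p]
        k = kcounts[j]
        for a in range(k):
            b = a + np.random.randint(0, m - a)
            tmp = males[s + a]
            males[s + a] = males[s + b]
            males[s + b] = tmp
            mate_idx[indptr[j] + a] = males[s + a]
    return mothers, indptr, mate_idx


@njit(cache=True)
def birth_kernel(sex, patch, aa, ab, d0a, d1a, d0b, d1b,
                 mothers, indptr, mate_idx, patch_counts, caps,
                 c, p_drive, tau, sterile, mut_rate,
                 step_d0, step_d1, two_locus,
                 max_litter, litter_offset, litter_rate):
    """Produce this turn's newborns from the mating table.

    Per mother: litter size from the logistic rule at her patch's current
    occupancy; per offspring, independently: a sire drawn with weight ``c``
    per t-carrying mate and 1 per +/+ mate (in the sterile variant t/t
    males are dropped from the pool first; if every fertile mate is a
    zero-weight t-carrier the c -> 0 limit, uniform among them, applies);
    one chromosome from each parent (drive biases the sire's choice, no
    recombination); t/t embryos survive with probability ``tau``; each
    inherited locus then mutates with probability ``mut_rate``; sex is a
    fair flip and in heterozygotes the t haplotype is dominant, otherwise
    dominance is a fair flip.

    Returns the newborn arrays (sex, patch, allele_a, allele_b, d0a, d1a,
    d0b, d1b, dom); haplotype *a* is paternal.
    """
    cap = mothers.size * max_litter
    b_sex = np.empty(cap, np.uint8)
    b_patch = np.empty(cap, np.int64)
    b_aa = np.empty(cap, np.uint8)
    b_ab = np.empty(cap, np.uint8)
    b_d0a = np.empty(cap, np.float64)
    b_d1a = np.empty(cap, np.float64)
    b_d0b = np.empty(cap, np.float64)
    b_d1b = np.empty(cap, np.float64)
    b_dom = np.empty(cap, np.uint8)
    nb = 0
    for j in range(mothers.size):
        mom = mothers[j]
        p = patch[mom]
        litter = litter_size_kernel(patch_counts[p], caps[p],
                                    max_litter, litter_offset, litter_rate)
        if litter <= 0:
            continue
        s = indptr[j]
        e = indptr[j + 1]
        n_t = 0
        n_plus = 0
        for q in range(s, e):
            g = aa[mate_idx[q]] + ab[mate_idx[q]]
            if sterile and g == 2:
                continue
            if g >= 1:
                n_t += 1
            else:
                n_plus += 1
        if n_t + n_plus == 0:
            continue
        denom = c * n_t + n_plus
        for _ in range(litter):
            sire = -1
            if denom > 0.0:
                u = np.random.random() * denom
                acc = 0.0
                for q in range(s, e):
                    m_i = mate_idx[q]
                    g = aa[m_i] + ab[m_i]
                    if sterile and g == 2:
                        continue
                    acc += c if g >= 1 else 1.0
                    sire = m_i  # falls back to the last fertile mate
                    if u < acc:
                        break
            else:
                pick = np.random.randint(0, n_t)
                kk = 0
                for q in range(s, e):
                    m_i = mate_idx[q]
                    g = aa[m_i] + ab[m_i]
                    if sterile and g == 2:
                        continue
                    if kk == pick:
                        sire = m_i
                        break
                    kk += 1
            hp = choose_transmitted(aa[sire], ab[sire], p_drive, True)
            hm = choose_transmitted(aa[mom], ab[mom], p_drive, False)
            if hp == 0:
                al_p = aa[sire]
                pd0 = d0a[sire]
                pd1 = d1a[sire]
            else:
                al_p = ab[sire]
                pd0 = d0b[sire]
                pd1 = d1b[sire]
            if hm == 0:
                al_m = aa[mom]
                md0 = d0a[mom]
                md1 = d1a[mom]
            else:
                al_m = ab[mom]
                md0 = d0b[mom]
                md1 = d1b[mom]
            if al_p == DRIVER and al_m == DRIVER:
                if np.random.random() >= tau:
                    continue
            if mut_rate > 0.0:
                pd0 = mutate_locus(pd0, mut_rate, step_d0, 0.0, 1.0)
                md0 = mutate_locus(md0, mut_rate, step_d0, 0.0, 1.0)
                if two_locus:
                    pd1 = mutate_locus(pd1, mut_rate, step_d1, -1.0, 1.0)
                    md1 = mutate_locus(md1, mut_rate, step_d1, -1.0, 1.0)
            b_sex[nb] = 1 if np.random.random() < 0.5 else 0
            b_patch[nb] = p
            b_aa[nb] = al_p
            b_ab[nb] = al_m
            b_d0a[nb] = pd0
            b_d1a[nb] = pd1
            b_d0b[nb] = md0
            b_d1b[nb] = md1
            if al_p != al_m:
                b_dom[nb] = 0 if al_p == DRIVER else 1
            else:
                b_dom[nb] = np.random.randint(0, 2)
            nb += 1
    return (b_sex[:nb], b_patch[:nb], b_aa[:nb], b_ab[:nb],
            b_d0a[:nb], b_d1a[:nb], b_d0b[:nb], b_d1b[:nb], b_dom[:nb])


@njit(cache=True)
def mortality_kernel(age, patch, alive, caps, m_turn):
    """Two-stage mortality, then aging.

    Stage 1: every mouse (newborns included) dies independently with
    probability ``m_turn``. Stage 2: on each patch still holding more than
    its capacity, exactly the excess is removed uniformly at random,
    blind to traits, sex and age. Survivors age by one turn.
    """
    n_patches = caps.size
    n = age.size
    if m_turn > 0.0:
        for i in range(n):
            if alive[i] and np.random.random() < m_turn:
                alive[i] = False
    counts = np.zeros(n_patches, np.int64)
    for i in range(n):
        if alive[i]:
            counts[patch[i]] += 1
    starts = np.zeros(n_patches + 1, np.int64)
    for p in range(n_patches):
        starts[p + 1] = starts[p] + counts[p]
    order = np.empty(starts[n_patches], np.int64)
    fill = starts[:n_patches].copy()
    for i in range(n):
        if alive[i]:
            pp = patch[i]
            order[fill[pp]] = i
            fill[pp] += 1
    for p in range(n_patches):
        excess = counts[p] - caps[p]
        if excess > 0:
            s = starts[p]
            m = counts[p]
            for a in range(excess):
                b = a + np.random.randint(0, m - a)
                tmp = order[s + a]
                order[s + a] = order[s + b]
                order[s + b] = tmp
                alive[order[s + a]] = False
    for i in range(n):
        if alive[i]:
            age[i] += 1


# ---------------------------------------------------------------------------
# Initialization and t introduction
# ---------------------------------------------------------------------------

@njit(cache=True)
def init_population_kernel(n, n_patches):
    """Founders: age 1, all +/+, fair independent sex draws, uniform patch,
    each haplotype's d0 uniform on [0, 1], d1 = 0, dominance a fair flip."""
    sex = np.empty(n, np.uint8)
    age = np.ones(n, np.int64)
    patch = np.empty(n, np.int64)
    aa = np.zeros(n, np.uint8)
    ab = np.zeros(n, np.uint8)
    d0a = np.empty(n, np.float64)
    d1a = np.zeros(n, np.float64)
    d0b = np.empty(n, np.float64)
    d1b = np.zeros(n, np.float64)
    dom = np.empty(n, np.uint8)
    for i in range(n):
        sex[i] = 1 if np.random.random() < 0.5 else 0
        patch[i] = np.random.randint(0, n_patches)
        d0a[i] = np.random.random()
        d0b[i] = np.random.random()
        dom[i] = np.random.randint(0, 2)
    return sex, age, patch, aa, ab, d0a, d1a, d0b, d1b, dom


@njit(cache=True)
def introduce_t_kernel(aa, ab, dom):
    """Convert floor(N/2) uniformly chosen mice from +/+ to +/t by flipping a
    uniformly chosen one of their two chromosomes to t, keeping its
    dispersal loci untouched; the t haplotype becomes dominant. Returns the
    number converted."""
    n = aa.size
    k = n // 2
    idx = np.arange(n)
    for a in range(k):
        b = a + np.random.randint(0, n - a)
        tmp = idx[a]
        idx[a] = idx[b]
        idx[b] = tmp
        i = idx[a]
        if np.random.random() < 0.5:
            aa[i] = DRIVER
            dom[i] = 0
        else:
            ab[i] = DRIVER
            dom[i] = 1
    return k


# ---------------------------------------------------------------------------
# One full turn
# ---------------------------------------------------------------------------

@njit(cache=True)
def turn_kernel(sex, age, patch, aa, ab, d0a, d1a, d0b, d1b, dom, caps,
                mean_k, sigma_k0, sigma_kx, alpha, m_disp, m_turn,
                c, p_drive, tau, sterile, mut_rate, step_d0, step_d1,
                two_locus, max_litter, litter_offset, litter_rate):
    """Run one turn in the fixed order capacity redraw -> dispersal ->
    mating -> birth -> mortality/aging, each stage completing for all
    individuals before the next begins. ``caps`` is updated in place;
    the compacted survivor arrays are returned."""
    n_patches = caps.size
    redraw_capacities(caps, mean_k, sigma_k0, sigma_kx)
    n = sex.size
    alive = np.ones(n, np.bool_)
    density = np.zeros(n_patches, np.int64)
    for i in range(n):
        density[patch[i]] += 1
    dispersal_kernel(age, patch, d0a, d1a, d0b, d1b, dom, alive, density,
                     m_disp)
    mothers, indptr, mate_idx = mating_kernel(sex, age, patch, alive,
                                              n_patches, alpha)
    counts = np.zeros(n_patches, np.int64)
    for i in range(n):
        if alive[i]:
            counts[patch[i]] += 1
    born = birth_kernel(sex, patch, aa, ab, d0a, d1a, d0b, d1b,
                        mothers, indptr, mate_idx, counts, caps,
                        c, p_drive, tau, sterile, mut_rate,
                        step_d0, step_d1, two_locus,
                        max_litter, litter_offset, litter_rate)
    nb = born[0].size
    n2 = n + nb
    sex2 = np.empty(n2, np.uint8)
    age2 = np.empty(n2, np.int64)
    patch2 = np.empty(n2, np.int64)
    aa2 = np.empty(n2, np.uint8)
    ab2 = np.empty(n2, np.uint8)
    d0a2 = np.empty(n2, np.float64)
    d1a2 = np.empty(n2, np.float64)
    d0b2 = np.empty(n2, np.float64)
    d1b2 = np.empty(n2, np.float64)
    dom2 = np.empty(n2, np.uint8)
    alive2 = np.empty(n2, np.bool_)
    for i in range(n):
        sex2[i] = sex[i]
        age2[i] = age[i]
        patch2[i] = patch[i]
        aa2[i] = aa[i]
        ab2[i] = ab[i]
        d0a2[i] = d0a[i]
        d1a2[i] = d1a[i]
        d0b2[i] = d0b[i]
        d1b2[i] = d1b[i]
        dom2[i] = dom[i]
        alive2[i] = alive[i]
    for q in range(nb):
        i = n + q
        sex2[i] = born[0][q]
        age2[i] = 0
        patch2[i] = born[1][q]
        aa2[i] = born[2][q]
        ab2[i] = born[3][q]
        d0a2[i] = born[4][q]
        d1a2[i] = born[5][q]
        d0b2[i] = born[6][q]
        d1b2[i] = born[7][q]
        dom2[i] = born[8][q]
        alive2[i] = True
    mortality_kernel(age2, patch2, alive2, caps, m_turn)
    keep = np.where(alive2)[0]
    return (sex2[keep], age2[keep], patch2[keep], aa2[keep], ab2[keep],
            d0a2[keep], d1a2[keep], d0b2[keep], d1b2[keep], dom2[keep])
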
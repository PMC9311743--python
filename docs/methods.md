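# Methods

## Model

`drivedisp` is an individual-based model of a driving supergene — the house
mouse *t* haplotype — competing with its homologous wildtype chromosome in a
metapopulation, while both chromosomes carry heritable dispersal loci that
evolve by mutation, drift and selection.

**World.** S = 49 habitat patches form an island system: the only movement
between patches is dispersal, and mice on a patch share one well-mixed
location. Each patch has an integer carrying capacity K_p drawn at
initialization from Normal(μ = 50, σ_K0), redrawn until it falls inside
μ ± 2σ_K0, and rounded. Every turn K_p is redrawn from
Normal(current K_p, σ_Kx) under the same bounds — a bounded random walk that
makes capacity temporally autocorrelated. σ_K0 is the spatial and σ_Kx the
temporal heterogeneity of the environment. Capacities are integers because
the density-dependent mortality rule removes exactly N_p − K_p mice. When
σ_K0 = 0 the admissible interval collapses to {μ}, so capacities are held at
μ regardless of σ_Kx (the limiting behaviour of the redraw-until-inside
rule, which would otherwise never terminate).

**Mice.** Diploid, sexed, aged in turns. Each chromosome carries the
driver/wildtype allele plus a dispersal intercept D0 ∈ [0, 1] and (in
two-locus mode) a density slope D1 ∈ [−1, 1]. There is no recombination: a
parent transmits one whole chromosome. One haplotype per mouse is
*dominant* and alone determines the dispersal phenotype; in +/*t* the *t*
haplotype is always dominant, in homozygotes one haplotype is chosen
uniformly at birth and stored for life (dominance is a property of the
individual, not re-drawn per decision).

**Turn procedure.** Capacity redraw → dispersal → mating → birth →
mortality/aging; each behaviour completes for every individual before the
next begins. The capacity redraw sits at the start of the turn so that the
density mice evaluate and the capacity governing the turn's births and
mortality refer to the same world state.

* *Dispersal.* Only mice of age exactly 1 disperse. Each compares a uniform
  draw with clamp(D0 + D1·N_p, 0, 1) evaluated at its patch's density at
  the start of the turn (the snapshot is not updated as others leave).
  Dispersers die with probability M_disp = 0.3; survivors move to a patch
  chosen uniformly among the other S − 1 (applying death at departure or
  arrival is observationally identical). Clamping the linear norm into
  [0, 1] is behaviourally identical to comparing the unclamped value with a
  uniform draw.
* *Mating.* Every female of age ≥ 1 on a patch with m ≥ 1 adult males mates
  1 + Binomial(m − 1, α) times: the first approaching male is always
  accepted, each later one with probability α, and because each female sees
  the males in fresh random order the accepted set, given its size, is a
  uniform subset — which is how it is sampled. Males are unconstrained in
  matings; polyandry therefore rises with local density.
* *Birth.* A mated female conceives round(6 / (1 + e^{0.1(24 + N_p − K_p)}))
  offspring — 0 at capacity, exactly 1 at one below capacity, saturating at
  6 — using the post-dispersal census of her patch (all pregnancies start
  before any birth of the turn, so no same-turn newborn is counted). Each
  offspring independently draws a sire among the mother's mates with weight
  c = P_t-sperm/(1 − P_t-sperm) per *t*-carrying mate and 1 per +/+ mate
  (Pt-sperm = 0.15 by default, i.e. c = 3/17, the siring probability against
  a single wildtype rival). In the sterile-male variant, viable t/t males
  are removed from the sire pool (but still consume matings). If every
  fertile mate is a *t*-carrier with weight 0 (the P_t-sperm = 0 corner of
  the trait sweeps), the c → 0 limit — uniform among them — applies; this
  also reproduces the single-mate rule with no special case. A +/*t* sire
  transmits *t* with probability P_drive = 0.9, everyone else transmits a
  fair coin flip. t/t embryos survive with probability τ. Each inherited
  locus then mutates independently with the scheduled probability, moving
  ±10⁻³ (D0) or ±2·10⁻⁵ (D1) and clamping at the range boundary; the steps
  differ so that one slope mutation changes the propensity at mean density
  (50) by the same 10⁻³ as one intercept mutation does at density 0. Sex is
  a fair independent draw.
* *Mortality.* Every mouse — newborns included — dies with M_turn = 0.25;
  then each patch above capacity loses exactly the excess, uniformly at
  random with respect to traits, sex and age. Survivors age by one turn.

**Protocol.** 5,000 +/+ founders of age 1 are scattered uniformly; each
haplotype's D0 is uniform on [0, 1] and D1 = 0. After 10% of the turns,
half of all mice (rounded down) have one uniformly chosen chromosome
flipped to *t* (loci untouched, *t* becomes dominant), putting *t* at
exactly ¼ of chromosomes. The per-locus mutation rate ramps linearly from
1.0 at turn 0 down to 10⁻³ at the introduction turn, snaps back to 1.0 as
the driver enters, and ramps down to 10⁻³ again by the final turn: the
first burst lets the wildtype find its optimum before competition begins,
the second gives both chromosomes mutational input while they compete. (At
the single introduction turn itself the reset value 1.0 is used.) Runs end
early when *t*, +, or the whole population hits zero after the
introduction; only runs that complete with both chromosome classes alive
("coexistence") contribute evolved phenotypes.

**Measurement.** For each condition, all chromosomes of all living mice
over the final 10 turns of every coexisting replicate are pooled (an
individual surviving several of those turns is sampled repeatedly) and
subsampled uniformly to at most 100,000 per allele class. The dispersal
propensity of each chromosome is its clamped reaction norm evaluated at a
reference density — low = μ − σ_K0 (35) and high = μ + σ_K0 (65) under the
natural condition, or the raw D0 for one-locus chromosomes — and the
*t*-minus-+ mean difference is reported with a 95% CI from a t distribution
with df = n_t + n_plus and SE = √(var_t/n_t + var_+/n_+) (a
Welch–Satterthwaite df is available behind a flag for sensitivity
analysis). The densities are evaluated at exactly μ ∓ σ_K0; the ±1 band
around them is treated as display binning, not averaging. A sweep cell is
"fixated" when no replicate coexists, and shows a "clear" difference when
the CI excludes zero. Note that because the pooled chromosomes are highly
correlated (the same individuals recur across the 10 turns and contribute
both chromosomes), these CIs quantify sampling noise of the pool, not
between-replicate variation, and are much narrower than replicate-level
intervals.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_patches` | 49 | number of island patches S |
| `mean_k` | 50 | mean carrying capacity μ |
| `sigma_k0` | 15 | spatial capacity SD; bounds are μ ± 2σ_K0 |
| `sigma_kx` | 15 | temporal capacity SD (per-turn redraw) |
| `alpha` | 0.02 | remating acceptance probability (polyandry) |
| `tau` | 0 | t/t embryo viability |
| `p_drive` | 0.9 | transmission probability of *t* from +/*t* males |
| `p_t_sperm` | 0.15 | siring probability vs one +/+ rival (c = 3/17) |
| `m_disp` | 0.3 | dispersal mortality |
| `m_turn` | 0.25 | per-turn background mortality |
| `init_pop` | 5,000 | founders |
| `t_intro_turn_fraction` | 0.1 | when half the mice become +/*t* |
| `n_turns` | 100,000 | run length (1,000,000 for full two-locus runs) |
| `mut_rate_max/min` | 1.0 / 10⁻³ | mutation-schedule endpoints |
| `mut_step_d0/d1` | 10⁻³ / 2·10⁻⁵ | mutation step sizes |

The defaults are the "natural condition" {σ_K0 = 15, σ_Kx = 15, α = 0.02,
τ = 0}: moderate environmental heterogeneity, common polyandry, fully
lethal homozygotes. Scenario grids vary α × τ, σ_K0 × σ_Kx (6 × 6),
τ × P_drive (no polyandry) and P_t-sperm × P_drive (τ = 0), the latter two
in 0.05 increments.

## Problem sizes of the shipped experiments

Full-scale runs are 100,000 turns (one-locus) and 1,000,000 turns
(two-locus). The test suite and `scripts/acceptance.py` use desk-scale
sizes chosen so the whole battery runs on one CPU in minutes:

* one-locus natural condition: 5 replicates × 20,000 turns × 5,000
  founders. This already reproduces the full-scale evolved difference
  (+0.07) almost exactly.
* two-locus conditions (natural and sterile-male): 3–5 replicates ×
  100,000 turns (60,000 in the test suite). Slope (D1) evolution is slow —
  its mutation step is 50× smaller than D0's — which is why the original
  design runs two-locus models 10× longer; at 100,000 turns the low/high
  density differences are already in the full-scale range, while the
  heterozygote frequency is still descending toward its long-run value
  (~0.43–0.45 at 100,000 turns vs ~0.32 at full scale) as the driver's costly
  dispersal phenotype keeps building up. Desk-scale runs therefore
  overestimate the equilibrium +/*t* frequency by roughly 0.1.
* the weakened-costs condition (α = 0, τ = 0.5, one-locus) runs at its full
  100,000-turn design: the reversal of the dispersal difference (wildtype
  dispersing more) develops only late in the mutation schedule (pilot
  trajectory: +0.004 at 20k, +0.05 at 60k, −0.13 at 100k turns).

## What the simulation does and does not emulate

The model reproduces the drive system's known traits (biased transmission,
homozygote inviability or male sterility, sperm-competition disadvantage,
density-dependent polyandry) inside a fluctuating island world. It omits,
deliberately: recombination between the driver region and the dispersal
loci (the *t* is an inversion-locked supergene), sex-specific dispersal
norms, distance-structured dispersal (movement is global), within-turn
scheduling beyond the fixed behaviour order, and any explicit genetics of
the dispersal trait beyond two additive-step loci. Passing tests show that
the *mechanisms encoded here* generate the reported dispersal differences;
they cannot show that real mouse dispersal is governed by these loci.

## Numerical and implementation choices

* The per-turn life cycle is compiled with numba; all randomness flows
  through one seeded single-threaded RNG stream per replicate, so a seed
  fixes the trajectory bit for bit. Per-replicate seeds are derived
  counter-style from (base seed, condition index, replicate index) so
  adding replicates never perturbs existing ones.
* Mate sets are sampled by drawing the count 1 + Binomial(m − 1, α) first
  and then a uniform subset of that size (partial Fisher–Yates); by
  exchangeability of the random approach order this is distribution-exact.
* Individual processing order within a stage is statistically irrelevant
  here (decisions depend on the turn-start snapshot, males are
  unconstrained, litter sizes use the pre-birth census), so stages iterate
  in array order and use explicit uniform sampling wherever a uniform
  choice among individuals is required (mates, capacity-excess removal).
* Capacity draws are rejected on the continuous value and then rounded;
  litter sizes round half away from zero (no representable half-integer
  cases arise at integer N_p, K_p).
* Founder sexes are independent fair draws, not an exact 50/50 split;
  founder D0 is drawn per chromosome, not per individual.

## Known limitations

* Desk-scale runs understate slope divergence and overstate heterozygote
  frequency relative to full-scale runs (see problem sizes above).
* The chromosome-pool CIs treat correlated chromosomes as independent (by
  construction of the measurement layer); replicate-level resampling would
  give wider, more conservative intervals.
* Replicates run sequentially; the sweep layer is trivially
  parallelizable across replicates but no scheduler integration is
  provided.
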
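# Methods

## The scientific setting

Androdioecious *Caenorhabditis* species (such as *C. elegans*) consist of
self-fertile hermaphrodites and rare males. Selfed broods are ~0.2% male —
the spontaneous X-chromosome nondisjunction rate — while outcrossed broods
are 50% male, because half of paternal sperm carry no X. Male numbers can
therefore only be sustained by outcrossing. Grouped males secrete an
ascaroside pheromone that is toxic to other males: it shortens their
lifespan and, when exposure starts from the egg stage, suppresses their
fertility with age. The package quantifies the demographic consequence:
pheromone-suppressed males sire fewer cross progeny, so the male fraction
decays across generations and the population returns to a primarily
hermaphroditic state.

## Progeny bookkeeping and the relative progeny factor

A cohort of N0 males (default 60) mates over a window of adult days
(Day 1–6). Each male has an equal chance of mating each day; there is no
male attrition inside the window (death during six days is not part of the
bookkeeping — it acts on longer time scales and is deliberately excluded so
the factor isolates the fertility effect). The expected total progeny for a
condition is

    T = Σ_d N0 · f_d · k_d

with f_d the fraction of males fertile on day d and k_d the progeny per
successful mating. The relative progeny factor is r = T_treated / T_control.
It is invariant to N0 and to any common rescaling of the k_d, and equals 1
for identical schedules.

Only the Day 4 and Day 6 fertile fractions are published as numbers
(control 82% and 69%; treated 69% and 29%); Day 1 fertility defaults to 1.0
and intermediate days are filled by linear interpolation, clipped to [0, 1].
This is an explicit assumption, overridable through the anchor arguments.
The per-day progeny counts exist only as a bar chart, so the packaged
progeny anchors are a flat placeholder: recomputing r from the interpolated
schedules gives ≈0.82, and the published value r = 0.768 — obtained with the
measured per-day progeny — is used as the authoritative default wherever r
is consumed downstream.

## The male-fraction recursion

Starting from a male population explosion (m0 = 50% males), the male
fraction follows

    m_X = m0 · r^X.

With r = 0.768, one generation gives 38.4%, and the fraction first falls
below the "primarily hermaphroditic" threshold at generation 15. The
threshold is not published; 1% is this package's convention (chosen as the
value consistent with the reported ~15-generation time scale; the 0.2%
selfing baseline is available as an alternative through the `threshold`
argument). `generations_to_threshold` iterates the recursion and agrees
with ceil(log(threshold/m0)/log r) except on exact-threshold landings,
where the iterative strict-inequality definition is authoritative.
`compare_to_benchmark` converts generations to days at 3 d/generation,
derived from the observed equivalence of 12–20 days and 4–7 generations for
male disappearance in wild-type populations; the model's 15 generations
(~45 days) is slower than that benchmark, consistent with pheromone killing
acting alongside other male-removal forces rather than alone.

## Stochastic mating-system extension

Generations are discrete and non-overlapping. With H hermaphrodites and M
males, each hermaphrodite mates with probability

    p = min(1, c·M/H) · r

where c (encounter efficacy, default 10) is a free parameter — the
underlying studies specify no encounter model — and r multiplies as a
fertility efficacy (1 for control runs). Mated hermaphrodites produce a
full brood (default 238, the measured self brood size, which pheromone does
not change) of cross offspring, male with probability 0.5; unmated
hermaphrodites self the same brood, male with probability 0.002. Offspring
pools above the carrying capacity are downsampled without replacement
(hypergeometric), which preserves the sex-ratio expectation. A population
without hermaphrodites cannot continue and the trajectory is truncated with
an explicit `extinct` flag.

The exact one-generation mean map is m' = p·q_cross + (1−p)·q_self with
p = min(1, c·m/(1−m))·r; `expected_trajectory` iterates it and serves as
the deterministic oracle for the simulation. In the scarce-male,
zero-selfing limit the map is geometric with effective ratio c·r·q_cross,
recovering the m0·r^X form; at finite male fractions it carries a 1/(1−m)
correction and, under saturating encounters, a constant plateau — both are
properties of the min(1, c·M/H) encounter rule, not simulation error. With
mating disabled (c = 0) the male fraction converges to the selfing rate;
with saturated mating and r = 1 it fluctuates around 0.5 with variance
shrinking as 1/N.

## Survival statistics

- **Kaplan-Meier**: product-limit estimator over distinct death days, with
  the standard tie convention that deaths precede censorings on the same
  day. With no censoring it reproduces the empirical survival function and
  its restricted mean equals the arithmetic mean of death days.
- **Mean ± SE**: uncensored data use the arithmetic mean with SE = sd/√n
  (the figure-legend presentation). Censored data switch automatically to
  the KM restricted mean up to the last death with a Greenwood-type SE; the
  emulated assays follow every animal to death, so the switch exists to
  keep the operation total.
- **Log-rank (Mantel-Cox)**: observed-minus-expected deaths at each
  distinct death time with hypergeometric variance-covariance, chi-square
  reference with (groups − 1) df; the covariance matrix is inverted with a
  pseudo-inverse for degenerate layouts. Validated against an established
  survival package to ≥6 significant digits on random censored datasets,
  and for its type-I error rate (within [0.03, 0.07] at α = 0.05 over 1000
  null simulations).
- **Percent reduction**: 100·(1 − mean_trt/mean_ctrl); antitone in the
  treated mean and scale-invariant.
- **Unpaired t test**: pooled-variance Student by default (df n1+n2−2),
  Welch via flag (replicate-level variances in the fertility comparisons
  are unequal). Both samples constant with equal means → (t, df, p) =
  (0, df, 1) by convention.
- **Hypergeometric overlap**: upper tail P(X ≥ k) for the shared count of
  two gene lists drawn independently from a finite universe; validated by
  exhaustive enumeration for universes ≤ 12. The sizes behind the published
  overlap p-value are not printed, so that value is not reproduced.
- Two-sided p-values throughout; no multiple-testing correction (the
  emulated analyses report per-comparison p-values).

## Chemotaxis

CI = (n_super − n_ctrl)/(n_total − n_origin) per plate; worms elsewhere on
the plate count only in the denominator's total. Aggregation is the
unweighted plate mean ± SEM; a single plate reports SEM 0 with a warning.
Group comparison is the unpaired t test or a label-permutation test on
|mean difference| (exact enumeration when ≤12 plates in total, otherwise
10,000 resamples with an add-one estimate). Whether published comparisons
were computed per plate or per replicate is ambiguous; both aggregations
are possible by passing replicate-level values to the t test directly.

## Synthetic-data generator

Mortality is Gompertz: h(t) = a·e^{bt}, S(t) = exp(−(a/b)(e^{bt}−1)),
sampled by inverse transform; b = 0 recovers the exponential for analytic
tests. Published cohorts are summarized only as mean ± SE, so the hazard
shape is a modelling choice; `calibrate_hazard` root-finds a at fixed b so
the quadrature mean hits a target to ~1e-6 d, and b is chosen per cohort so
the simulated SE of the mean matches the printed legend SE (0.5/d for
solitary males at 12.0 ± 0.4 d, n = 40; 0.7/d for grouped males at
7.7 ± 0.2 d, n = 80 — aging rates in the range reported for worm
mortality). Generated lifespans are uncensored by default (the emulated
assays follow all animals to death); `censor_day` exercises the censored
paths. Chemotaxis plates are multinomial over
{supernatant, control, origin, elsewhere}; offspring sexes are Bernoulli
at the selfing or crossing male rate. Every generator takes a mandatory
seed and is bit-reproducible.

What the generator does *not* emulate: inter-animal frailty beyond the
Gompertz shape, day-granular scoring ties (times are continuous unless the
caller rounds), plate-to-plate density effects, and any transcriptome,
body-size or staining phenotype. Passing tests therefore show the
statistics are implemented correctly under the stated models, not that the
models capture every feature of real assay data.

## Problem sizes and numerical choices

Monte-Carlo checks use 10^5 lifespans for calibration recovery, 10^6
offspring draws for the sex-ratio rates, 200 seeds × 8 generations at
carrying capacity 2×10^4 for the stochastic-vs-mean-field comparison, and
1000 replicates for type-I-error rates — sizes at which 3-standard-error
bands are decisive for the effects of interest. Root-finding brackets the
Gompertz baseline rate on a log grid (Brent, xtol 1e-12). Permutation
p-values treat statistics tied with the observed value (within 1e-12) as
at least as extreme. The log-rank statistic is clamped at 0 against
negative floating-point round-off.

## Known limitations

- The recursion treats generations as discrete and synchronous and r as
  constant across generations; real populations overlap generations and r
  depends on age structure.
- The encounter model min(1, c·M/H) is the simplest male-limited saturating
  choice; c is not identified by any published measurement.
- Mating-induced male death and hermaphrodite responses to males — forces
  the underlying work discusses as acting in tandem with pheromone
  toxicity — are intentionally outside the default model.
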
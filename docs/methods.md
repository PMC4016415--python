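# Methods

## Model

`lifecourse` models the yearly evolution of individual morbidity as a
first-order, time-homogeneous (stationary) discrete-time Markov chain over
seven states: six aggregated Clinical Risk Group (CRG) core health statuses
— E1 healthy, E2 significant acute disease, E34 minor chronic disease, E56
significant chronic disease in one or two organ systems, E79 significant
chronic disease in three or more organ systems or catastrophic conditions,
E8 dominant and metastatic malignancies — plus an explicit absorbing death
state (DEAD). The fundamental assumption is that the health state of a
person in a given year depends only on the state the year before; dynamics
are stratified by gender and ten age bands (`<1`, `1-14`, `15-24`, …,
`75-84`, `>=85`, encoded as half-open intervals so every completed age
maps to one band), giving 20 row-stochastic 7×7 matrices.

### Estimation

Given a person-year panel, the one-year transition probabilities are the
maximum-likelihood frequency estimates pooled over the observed pairs of
consecutive years:

```
p̂_ij = Σ_t n_ij(t) / Σ_z Σ_t n_iz(t)
```

where `n_ij(t)` counts people in state *j* at *t* who were in state *i*
at *t−1*. A transition's stratum is set by the person's age at the origin
year, so one person can contribute to two strata across the study window.
Non-consecutive observations (gaps) are censoring and contribute nothing;
nothing is imputed. Origin rows with no observations fall back to an
identity (stay-in-state) row with a warning — the least informative choice
that keeps the matrix stochastic — and the DEAD row is always forced
absorbing.

Time-homogeneity is checked per stratum with the Anderson–Goodman
chi-squared test comparing each period's matrix to the pool:

```
X² = Σ_t Σ_ij n_i(t−1) (p̂_ij(t) − p̂_ij)² / p̂_ij  ~  χ²_{m(m−1)(P−1)}
```

with `m = 7` states and `P` period matrices. Cells with pooled probability
zero produce 0/0 terms; they are skipped, each removing `P−1` degrees of
freedom, and an origin row with no observations at all drops its entire
`(m−1)(P−1)` block (an unobserved row never had free parameters). Both the
nominal and the adjusted df are reported; the p-value uses the adjusted
df. The test informs but never blocks: non-stationary strata are logged
and the pooled matrices are still used downstream, because a single
pooled-parameter projection is the model's stated scope.

### Simulation engines

Two complementary engines project a birth cohort until extinction.

**Exact cohort propagation.** Real-valued state mass (default 100,000
newborns, split ≈96% healthy, 50.5% male) is multiplied through the
age-appropriate matrix, one year of age per cycle. Occupancy is recorded
at the start of each year: the year in which a person dies contributes its
origin state's person-year, and no half-cycle correction is applied.
Iteration stops when surviving mass falls below an extinction tolerance
(default 10⁻⁶ of the cohort) or at a hard cap of age 110, at which point
remaining mass moves to DEAD; without the cap the open-ended `>=85` band
never empties analytically. Expected years per state are occupancy sums
over ages divided by the initial gender mass; for an age-homogeneous chain
they equal the initial mix applied to the fundamental matrix `(I−Q)⁻¹`,
which the test suite uses as an independent linear-algebra oracle.
Matrices switch exactly at the band boundaries {1, 15, 25, …, 85}; the
resulting jumps in occupancy curves are a property of the band
construction and are deliberately not smoothed.

**Monte-Carlo microsimulation.** Individual pathways (default 10,000 per
gender) are drawn by inverse-CDF sampling: a uniform draw is compared to
the cumulative row probabilities in the fixed state order, with half-open
cumulative intervals so every draw maps to exactly one destination.
Seeding is hierarchical, one child stream per gender. The exact engine
gives the expectation; the microsimulation adds distributional information
(SD, quantiles, shape) at the price of sampling error in the mean.

### Costs

Each transient person-year is priced at the mean annual cost of its
(gender, age band, state) cell, in 2007 euros; cells with fewer
person-years than a threshold (default 30) fall back to the (gender,
state) aggregate. Because the attached cost is the cell *mean*, the spread
of the lifetime-cost distribution across simulated individuals reflects
the variability of health histories, not cost noise. Yearly mean cost
divides aggregate cost at an age by the *survivors* at that age (ages
past extinction are missing, not zero); lifetime mean cost divides the
whole-life aggregate by the initial cohort, and with age-invariant costs
equals the dot product of expected years with the cost means — an
identity the tests check to 1e-9. No discounting and no cost-growth
scenarios are applied.

Summary statistics: SD uses the n−1 denominator; quartiles use linear
interpolation between order statistics; skewness is the third
standardised central moment; kurtosis is reported in both raw and excess
conventions because published cost tables do not always declare which
they use. Degenerate (constant) distributions report NaN shape
statistics.

## Synthetic registry generator

No person-year registry with aggregated CRG states is publicly available,
so the generator produces one with a *known* ground truth against which
estimation and simulation are validated. It emulates: a population pyramid
with band shares of a 2007 reference cross-section; first-order Markov
state dynamics by construction; mortality increasing in both age band and
morbidity severity (multiplicative gradients plus absolute floors of 0.28
and 0.33 for E79/E8, whose real-world counterparts are short,
high-lethality episodes); chronic onset concentrated late in life
(age-cubic incidence for the severe states); an elevated healthy-to-acute
rate (×1.8) for women in the 15–44 bands, mirroring pregnancy-related
care; gamma-distributed annual costs parameterised by the published
gender×state means and a coefficient of variation (default 1.2, skewness
2.4); and in/out migration at 1%/year each, producing censoring without
death records (no quantitative migration rates are published; these
defaults are arbitrary and documented as such).

Defaults were calibrated once, at design time, to population anchors: a
cross-sectional healthy prevalence near 65% (accepted band 0.55–0.75),
~96% healthy newborns, a 50.5% male share, life expectancy at birth of
81.7 (F) / 77.9 (M) years, and per-state years and lifetime-cost
dispersion (CV ≈ 0.39 F / 0.45 M) on the scale of published tables. The
generator does not attempt to replicate any registry's actual transition
probabilities, which are not published.

What passing tests therefore show: the estimator recovers known matrices
at registry scale (≥95% of well-filled cells within 3 binomial SEs at
n = 50,000), the homogeneity test holds its nominal size under a truly
stationary generator (rejection rate within [0.01, 0.12] at α = 0.05 over
200 replicates), and the two engines agree (mean lifetime-cost gap ≤0.7%
at 10,000 pathways per gender with the prescribed seeds). What they do
not show: fidelity to any real population's transition structure, cost
heterogeneity within cells, non-stationary secular trends, or state
misclassification — all absent from the generator by design.

## Numerical choices and degenerate inputs

- One root seed spawns independent per-purpose streams (initial
  population, state paths, migration, costs), so toggling cost generation
  never perturbs health histories; the same seed yields byte-identical
  panels.
- Row sums are validated to 1e-10; matrix CSV round-trips are exact to 12
  decimals; costs round-trip to euro cents.
- Death is an explicit panel record in the year of death (no concurrent
  morbidity state is guessed for that year); absence without a DEAD
  record is censoring.
- Zero-survivor denominators yield missing values, never zero; empty
  (gender, state) cost cells borrow the pooled state mean with a warning,
  and a state with no costed person-years at all is an error.
- The single-period stationarity test and single-year panels are errors,
  not silent degenerate results.

## Problem sizes

Default analysis sizes: panels of 20,000 individuals over 2004–2007
(50,000 for the recovery study), cohorts of 100,000, 10,000 pathways per
gender, age cap 110. The closed-form oracles run chains to machine-level
extinction (tolerance 1e-12–1e-13, age caps up to 3,000) so truncation
error sits well below the 1e-6 comparison tolerance.

## Known limitations

- Stationarity is assumed for the whole life course; mortality trends and
  changing practice patterns violate this in the long run, so projections
  are conditional on the estimation window's dynamics.
- Costs are cell means: within-cell heterogeneity and proximity-to-death
  effects are out of scope.
- The Monte-Carlo mean at 10,000 pathways per gender carries a relative
  standard error of roughly 0.4–0.5% for lifetime cost, so its gap to the
  exact engine fluctuates on that scale across seeds.
- The generator's migration and within-band age assignments are uniform;
  real registries have structured entry/exit.
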
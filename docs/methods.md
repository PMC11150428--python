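# Methods

## Scope

`ckmrsim` studies one question: how do errors in length-based ageing —
a misspecified measurement-error SD and/or a vertically shifted growth
curve — propagate into close-kin mark-recapture (CKMR) estimates of
sex-specific adult abundance built from parent–offspring pairs (POPs)?
Everything is synthetic; the package contains both the data-generating
process (an agent-based, pedigree-tracking population simulator) and the
estimator, so every experiment is reproducible from a seed.

## Population model

Both species live on a yearly cycle with a fixed event order: **birth/
mating → sampling (final two years only) → survival → ageing**.  All
demographic rates are age- and time-invariant:

| parameter | simple | complex | meaning |
|---|---|---|---|
| a_max | 19 yr | 63 yr | certain death at the survival event of this age |
| α♀ / α♂ | 10 / 10 yr | 19 / 17 yr | knife-edge maturity |
| litter | always 2 | uniform {3,4,5,6} | pups per birth event |
| gestation | 0 yr | 1 yr | biennial breeding for the complex species |
| φ | 0.84661 | 0.88853 | annual survival, calibrated (below) |
| ℓ∞, k, a₀ | 163 cm, 0.0554 /yr, −8.27 yr | same | growth curve, both sexes |
| σℓ | 2.89 cm | same | true length measurement error SD |

Mating is random: every available mature female is paired with a uniformly
drawn mature male (males can father any number of litters); a complex-
species female mates only when not gestating and not having given birth
that same year, so her births fall every other year, the first at α♀ + 1.
Newborns (age 0, 50:50 sex) are exposed to survival in their birth year and
are sampleable in it, since sampling follows birthing and is unrelated to
age.

**Survival calibration.**  φ is not a free parameter: it is the root of
λ(φ) = 1 where λ is the dominant eigenvalue of the female projection
matrix for this exact event order (for the complex species the state space
is age × gestation status).  Equivalently, by Euler–Lotka at λ = 1, the
simple species solves Σ_{a=10..19} φ^a = 1 and the complex species solves
2.25 · Σ_{b=20,22,…,62} φ^b = 1; the eigenvalue route and these closed
forms agree to 10⁻⁶ and forward simulation at the calibrated φ keeps the
mean realised growth within 0.3 percentage points of 1.

**Founders.**  8,500 individuals enter year 1 with ages drawn from the
truncated-geometric stationary distribution on 1..a_max (pmf ∝ φ^a).  The
lower bound is 1 because, in this event order, age-0 animals exist only
between the birth and ageing stages — a pre-breeding census contains none.
Starting at the stationary structure avoids demographic transients; the
100-year horizon still guarantees every founder (whose parents are
unrecorded) is dead long before sampling.  Mature complex-species females
are initialised gestating with probability 1/2 so that the two alternating
breeding cohorts start balanced rather than artificially synchronised.

**Sampling.**  375 individuals per sampling year, uniform without
replacement within a year; recaptures across the two years are possible,
are kept in the data, and the pair formed by two captures of one individual
is an ordinary non-POP comparison.  Measured lengths are the growth-curve
length at the true age plus N(0, σℓ) noise, rounded half away from zero to
an integer cm.

**Truth for evaluation.**  A replicate's true abundance is the number of
living females (males) at or above their maturity age at the post-birth
point of the final year.  The realised growth rate is the geometric mean of
the yearly totals across the 100 years.

## Estimator

All n(n−1)/2 unordered record pairs are Bernoulli comparisons in a
pseudo-likelihood (pairs are not independent — an offspring has one mother —
so this is pseudo-, not true, likelihood; fine for point estimation under
sparse sampling).  Given ages, the directed parent probability is
m / N_{parent sex} with the kernel m as derived in the package docs
(maturity indicator; survival φ^Δt from the parent's capture to the
offspring's birth for mothers, to the mating year for complex fathers; a
φ⁻¹ gestation adjustment for complex mothers).  Ages are integer 0..a_max
and are marginalised under the assumed observation model:

* f(ℓ*|a): Normal(ℓ(a), σ²) integrated over the rounding cell
  [ℓ*−0.5, ℓ*+0.5] (written so the pmf is non-negative by construction);
* f(a): truncated geometric φ^a(1−φ)/(1−φ^(a_max+1)) — the stationary age
  distribution, using the **true** φ in every scenario (only σ and the
  curve are misspecified);
* f(a|ℓ*) ∝ f(ℓ*|a) f(a).

Because the pair probability depends on the records only through (sex,
capture year, measured length), comparisons are deduplicated into unique
keys with POP/non-POP multiplicities; the aggregated log-likelihood is
exactly the naive pairwise sum (unit-tested to 10⁻¹⁰).  Each key stores
age-marginalised coefficients (A, B) with P = A/N_{s1} + B/N_{s2}, computed
once per assumed model and reused across abundance evaluations.

**Optimisation and uncertainty.**  (log N♀, log N♂) is maximised by
Nelder–Mead from a start of twice the record count, with a small ladder of
rescaled restarts before declaring failure.  The observed information is a
central finite-difference Hessian (step 10⁻⁴ on the log scale); Var(N̂) =
N̂² Var(log N̂) by the delta method, and intervals are the standard 95%
log-normal construction C = exp(z₀.₉₇₅ √(ln(1 + cv²))), (N̂/C, N̂·C).  A fit
is recorded as non-converged — never raised — when the data are infeasible
under the assumed model (an observed length of zero probability, or an
observed POP with zero pair probability; discretised-Normal cells below
10⁻³⁰⁰ are treated as exact zeros), when no start succeeds, or when the
Hessian is not positive definite.  With double-precision arithmetic these
infeasibilities require extreme misspecification, so convergence failures
are far rarer here than in implementations that floor or underflow small
probabilities more aggressively; the exclusion rule (drop a scenario cell
when more than half its replicates fail) is implemented and exercised, but
at these study conditions most grid cells converge everywhere.

## Misspecification grid

Assumed σ ∈ {0.33, 0.67, 1, 1.33, 1.67} × 2.89 cm and assumed curve =
(1 + s) · ℓ(a) for s ∈ {−0.10, −0.05, 0, +0.05, +0.10} (a percentage shift
of expected length-at-age, implemented by scaling ℓ∞ — the reading that
keeps "shift the curve by 5%" uniform across ages), 25 scenarios labelled
`ME±XX:GC±YY`.  Each replicate is simulated once; only the assumed age
model changes across scenarios, so the comparison table is reused.
Per-cell metrics over converged replicates: mean/median error and relative
error, MAE, RMSE, 95% CI coverage, the empirical SE (the SD of estimation
*errors* across replicates — not of the estimates, whose spread would mix
in simulation stochasticity), and the mean model SE.

## Study conditions and problem sizes

The package defaults are the study conditions: 8,500 founders, 100 years,
2 × 375 samples, the parameter table above.  Ensemble sizes are the
package's own desk-scale choice: 300 replicates per species in
`scripts/acceptance.py` and 100 in the acceptance test suite (the full
design uses 1,000).  At 100–300 replicates, medians of relative error carry
Monte-Carlo noise of roughly ±2–4 percentage points and SD-based
quantities (empirical SEs, SE-honesty ratios) of roughly ±5–7% relative,
which is the main caveat when comparing single cells against reference
values.

## What the generator does and does not emulate

Simulated data contain exactly the structure the estimator assumes —
knife-edge maturity, constant survival, a shared deterministic growth
curve, random mating and age-independent sampling — plus the deliberate
scenario misspecifications.  Passing tests therefore demonstrate correct
implementation and the sensitivity of the method to ageing error, not
robustness to real-world violations: natural length-at-age variability
(beyond what σℓ jointly absorbs), selective sampling, population trend,
spatial or stock structure, age-dependent fecundity and fishing mortality
are all out of scope, as are half-sibling pairs and kinship-calling
uncertainty (kinship is read from the true pedigree).

## Numerical choices

* Rounding of lengths: half away from zero (lengths are positive, so this
  is ordinary commercial rounding).
* Posterior cache keyed by (model, length); coefficient matrices built by
  blocked matrix products over (parent sex, capture-year pair).
* Pair-probability excursions P ≥ 1 during optimisation are clipped inside
  log(1 − P); realistic abundances keep P ≪ 1.
* Replicate seeds are spawned from one master seed (`numpy` SeedSequence),
  so grids are reproducible and embarrassingly parallel.
* Degenerate inputs: fewer than two records, oversampling a dying
  population, and a species whose life history admits no stationary φ all
  raise immediately with explicit messages.

## Known limitations

* The pseudo-likelihood ignores the one-mother constraint across
  comparisons; with 750 samples from ~8,500 animals, sampling is not
  deeply sparse and model SEs can sit a few percent off the empirical
  error SD.  The effect is markedly sex-asymmetric in these ensembles:
  female-side model SEs track the empirical error SD to within a few
  percent, while male-side SEs undershoot it by roughly 15–20% (with
  correspondingly sub-nominal male CI coverage), driven by a heavy right
  tail of male estimates in replicates that happen to draw few paternal
  POPs.  The asymmetry survives replacing the lottery paternity draw by
  within-year father matching, so it is a property of the estimator on
  this data-generating process, not of the mating rule alone.
* The complex-species kernel treats every mature female as a potential
  mother with marginal probability 1/(φ N♀) even though only roughly half
  are available in any mating year; this is exact on average but ignores
  the availability heterogeneity.
* Abundance is assumed constant; drift in a replicate's true abundance
  over the sampled cohorts' birth years is absorbed into estimation error.
* Only gestation periods of 0 or 1 year are supported.
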
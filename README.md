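# ckmrsim

Close-kin mark-recapture (CKMR) estimates animal abundance from the
frequency of kin pairs among sampled individuals: every offspring
genetically "marks" its two parents, and comparing all sampled individuals
pairwise recaptures those marks.  For long-lived fish such as sharks, the
age of each sampled animal — which the method needs to place its birth year
— is usually inferred from a length measurement through a growth curve.
`ckmrsim` is a simulation laboratory for asking how wrong that inference can
be before the abundance estimates break: it pairs a pedigree-tracking,
agent-based population simulator with a parent–offspring-pair (POP)
pseudo-likelihood estimator that marginalises unknown ages over length, and
sweeps a grid of deliberately misspecified measurement-error SDs and growth
curves.

## The model

Two fictional shark species are simulated for 100 years (8,500 founders,
stationary demography, constant annual survival φ calibrated by projection-
matrix eigenvalue so that λ(φ) = 1): a *simple* annual breeder (litter of 2,
both sexes mature at 10, maximum age 19) and a *complex* biennial breeder
patterned on a grey reef shark population (litters of 3–6, one-year
gestation, male/female maturity 17/19, maximum age 63).  375 individuals
are sampled in each of the last two years; each record carries sex, capture
year and an integer length ℓ\* = round(ℓ(a) + ε), ε ~ N(0, σℓ²), with the
von Bertalanffy curve ℓ(a) = ℓ∞(1 − e^(−k(a−a₀))) (ℓ∞ = 163 cm,
k = 0.0554 yr⁻¹, a₀ = −8.27 yr, σℓ = 2.89 cm).

Sex-specific adult abundances (N♀, N♂), assumed constant, are estimated by
maximising the pairwise pseudo-log-likelihood

    ℓP(θ) = Σ_{i<j} ω_ij log P_ij + (1 − ω_ij) log(1 − P_ij),

where ω_ij marks the true POPs and, with ages marginalised over their
length-conditional posteriors f(a|ℓ\*) ∝ f(ℓ\*|a) f(a),

    P_ij = Σ_{a_i} Σ_{a_j} f(a_i|ℓ*_i) f(a_j|ℓ*_j)
           [ m(i→j) / N_{s_i} + m(j→i) / N_{s_j} ].

The kernel m encodes knife-edge maturity, survival from the parent's
capture to the offspring's conception, and (for the gestating species) the
φ⁻¹ gestation adjustment.  f(ℓ\*|a) is a discretised Normal around the
*assumed* growth curve; f(a) is the truncated-geometric stationary age
distribution.  Identical comparisons are deduplicated before optimisation;
standard errors come from the finite-difference Hessian on the log scale,
and intervals are 95% log-normal.

## Worked example

```python
import ckmrsim as ck

species = ck.simple_species()          # calibrates phi automatically
print(f"calibrated phi = {species.phi:.4f}")

sim = ck.run_simulation(species, seed=1)
print(f"{len(sim.samples)} records, {sim.n_pops} POPs, "
      f"{sim.recapture_count} recaptures, growth {sim.growth_rate:.4f}")

model = ck.age_model_for(species, ck.ScenarioSpec(1.0, 0.0))  # correct model
agg = ck.aggregate_comparisons(sim.samples, sim.pop_pairs, model, species)
fit = ck.fit_ckmr(agg)
print(f"N_f = {fit.N_f_hat:.0f} (SE {fit.se_f:.0f}), truth {sim.final_adults()[0]}")
print(f"N_m = {fit.N_m_hat:.0f} (SE {fit.se_m:.0f}), truth {sim.final_adults()[1]}")
```

prints

```
calibrated phi = 0.8466
750 records, 43 POPs, 22 recaptures, growth 0.9994
N_f = 614 (SE 105), truth 747
N_m = 1787 (SE 596), truth 720
```

The calibrated survival makes the population stationary (realised growth
0.9994 ≈ 1).  Among the 750 records the pedigree contains 43 true POPs; the
single-replicate estimates are noisy (the male estimate here overshoots its
truth by more than a factor of two, covered by its wide CI) — systematic
behaviour emerges at the ensemble level, e.g. via
`ck.run_scenario_grid(species, n_replicates=100, master_seed=0)` and
`ck.compute_metrics(...)`, which reproduce small positive median biases of a
few percent under correct specification, strong positive/negative biases
under down/up-shifted growth curves, and near-nominal CI coverage whenever
the curve is correct.

A CLI wraps the same functionality:

```
ckmrsim simulate --species simple --seed 1 --outdir out/
ckmrsim fit --samples out/samples.csv --pops out/pops.csv --species simple
ckmrsim grid --species complex --n-replicates 100 --seed 0 --outdir out/
ckmrsim metrics --fits out/fits.csv --out metrics.csv
```

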
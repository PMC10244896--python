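# sealrep

Carry-over effects of weaning size on adult reproduction in gray seals
(*Halichoerus grypus*): does a female's body length at weaning (L_w, cm,
measured ~4 weeks after birth) predict how well she reproduces as an adult,
decades later?

`sealrep` implements the two-track analysis this question requires on
longitudinal breeding-colony records, for quantitative ecologists working
with mark–resight data:

1. **Provisioning performance** — the weaning mass of each pup a female
   produces, modeled by linear mixed models with crossed random intercepts
   for mother and season,

       mass_{j,t} = β₀ + π₁·age_z + π₂·age²_z + π₃[parity] + π₄·I(sex=♀)
                    + π₅·L_w,z + α_i + η_t + ε_{j,t},

   fit by profiled maximum likelihood with LRT/AIC model comparison across
   a menu of L_w structures (none / linear / quadratic / L_w×parity /
   cohort offsets).

2. **Reproductive frequency** — the rate at which a female returns to breed,
   modeled as a latent Markov chain over states F (first-time breeder),
   B (breeder), N (nonbreeder) observed with imperfect detection (breeders
   sighted with probability p; nonbreeders undetectable). The transition
   into B is a mixed-effects logistic regression,

       logit ψ_{i,t}^{kB} = μ + λ₁·age_z + λ₂·age²_z + λ₃[k] + λ₅·L_w,z
                            + β_i + θ_t,

   with sum-to-zero previous-state effects λ₃. The exact marginal
   likelihood of each sighting history comes from a forward recursion over
   the latent states; fitting is Bayesian MCMC (forward-filter
   backward-sampling plus adaptive Metropolis), with WAIC model comparison,
   split-chain R-hat diagnostics, and the cost-of-reproduction posterior
   contrast ψ^{BB} − ψ^{NB}.

Because the motivating colony's records are not publicly deposited, the
package ships a synthetic-colony generator (`sealrep.simulate`) that
reproduces the study design — 363 recruited females from five cohorts
followed over 19 breeding seasons, L_w ≈ 112.7 ± 4.3 cm, recruitment at
ages 4–8, detection ≈ 0.975 — so the entire pipeline is testable end to
end by parameter recovery. `docs/methods.md` gives the full model and
sampler description.

## Worked example

```python
import numpy as np
from sealrep import (SimConfig, simulate_colony, filter_single_season,
                     build_design, fit_multistate, McmcConfig,
                     fit_mass_model, likelihood_ratio_test,
                     variance_partition, predict_mass_spread,
                     transition_summary, cost_contrast)

colony = simulate_colony(SimConfig(), seed=11)       # study-scale colony
histories = filter_single_season(colony.histories)   # >= 2 sightings
keep = {h.female_id for h in histories}
females = colony.female_table[colony.female_table.female_id.isin(keep)]
pups = colony.pup_table[colony.pup_table.female_id.isin(keep)]

# pup weaning mass: null vs linear weaning-length effect
null = fit_mass_model(pups, females, "null", standardizers=colony.standardizers)
lin = fit_mass_model(pups, females, "linear", standardizers=colony.standardizers)
stat, df, p = likelihood_ratio_test(null, lin)
print(f"pi5 = {dict(zip(lin.fixed_names, lin.fixed))['z_lw']:.2f} kg/sd,"
      f" LRT p = {p:.2e}")
print({k: round(100 * v, 1) for k, v in variance_partition(lin).items()})
print(f"spread 90->132 cm: {predict_mass_spread(lin)['spread_kg']:.1f} kg")

# breeding rate: multistate model with MCMC
design = build_design(histories, females, standardizers=colony.standardizers)
samples = fit_multistate(design, "linear",
                         McmcConfig(n_chains=3, n_burn=400, n_iter=1600,
                                    thin=2, seed=5))
print(f"lambda5 = {samples.stacked('lambda5').mean():.3f},"
      f" p = {samples.stacked('detection_p').mean():.3f}")
print(transition_summary(samples).round(3))
c = cost_contrast(samples)
print(f"psi_BB - psi_NB = {c.mean:.3f}, P(cost) = {c.prob_negative:.2f}")
```

Output from this exact script (seeds as shown):

```
pi5 = 0.93 kg/sd, LRT p = 8.64e-15
{'individual': 37.8, 'year': 13.5, 'residual': 48.7}
spread 90->132 cm: 9.1 kg
lambda5 = 0.532, p = 0.969
             mean     sd   q2.5    q50  q97.5
transition
psi_FB      0.810  0.076  0.630  0.818  0.924
psi_BB      0.894  0.042  0.795  0.900  0.957
psi_NB      0.924  0.035  0.838  0.929  0.974
psi_BB - psi_NB = -0.030, P(cost) = 0.98
```

Reading it: the colony was generated with a true weaning-length effect of
1.07 kg per sd of L_w on pup mass and 0.549 logits on breeding rate, with
detection 0.975; the fits recover all three within their uncertainty.
Individuals account for ~38% of the variance in pup mass and season for
~14%. The transition rates say a female that bred last year breeds again
with probability ~0.89, while one that skipped breeds with probability
~0.92 — the negative contrast is a slight cost of reproduction.
(Transition summaries are evaluated at the sample-mean covariates; exact
numbers vary with the seed.)

The same pipeline is available from the shell:

```bash
sealrep pipeline --seed 11 --out runs/demo          # simulate -> fit -> report
sealrep simulate --seed 3 --out runs/colony         # just the synthetic data
sealrep fit-mass --colony runs/colony --variant linear --out runs/mass
```

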
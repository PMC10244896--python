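# Methods

`sealrep` analyzes how a female gray seal's body length at weaning (L_w, cm,
measured ~4 weeks after birth) carries over into her adult reproductive
performance, using two model families over longitudinal breeding-colony
records: a linear mixed model of pup weaning mass (provisioning performance)
and a Bayesian mixed-effects multistate mark–recapture model of breeding
rate under imperfect detection. Because the motivating colony's data are not
publicly deposited, the package includes a synthetic-colony generator with
the same statistical structure; all validation is parameter recovery on
simulated colonies.

## Data model

Three plain-CSV tables flow through the pipeline:

* **Encounter matrix** (wide): one row per marked female, one column per
  breeding season, cells 0/1 = not sighted / sighted with a pup. A female's
  first 1 defines her *recruitment* occasion; the likelihood conditions on
  this first capture, so cells before it are structurally absent (`NA`
  allowed there and only there). Females sighted in a single season are
  dropped (`filter_single_season`): they may not have truly recruited and
  contribute no transition information. The filter is idempotent and the
  number of removed rows is logged.
* **Female table**: id, birth cohort (year), weaning length L_w (cm).
  Values outside [90, 132] cm warn but do not fail (the range observed in
  colony samples of this species).
* **Pup table**: mother id, season, pup sex, pup weaning mass (kg, > 0),
  maternal age. Parity (cumulative birth count, discretized 1 / 2 / 3+
  because the experience effect plateaus) is derived from the records, never
  stored.

### Covariate standardization

Age, age², L_w and L_w² each enter the models as a **separately z-scored
column**. Standardizing the squared term as its own column (rather than
squaring the z-scored value) is required for the model to behave sensibly at
the age extremes: with a raw quadratic on z-scored age, coefficient sets of
the magnitude this system produces (linear ≈ +14 kg/sd, quadratic ≈ −12
kg/sd²) would predict negative pup masses for the youngest mothers, whereas
separately standardized columns give the biologically expected
rise-then-plateau. By default the constants come from the analysis sample
(post-filter; ages pooled over all post-recruitment female-occasions, L_w
over females); a simulation's manifest stores the simulator-wide constants
and every fitting function accepts them, so recovery tests compare
like-for-like. Whether standardization should use the per-model sample or
the full sample is genuinely open; both are supported via the
`standardizers` argument, and all coefficients are reported on the
standardized scale with the constants recorded in the manifest.

## Provisioning model (pup weaning mass)

Weaning mass of pup *j* of female *i* in season *t* (kg):

    mass_{j,t} = b0 + pi1*age_z + pi2*age2_z + pi3[parity] + pi4*I(sex=female)
                 + (L_w terms) + alpha_i + eta_t + eps_{j,t}

with crossed random intercepts `alpha_i ~ N(0, sigma_alpha^2)` (female) and
`eta_t ~ N(0, sigma_eta^2)` (season), residual `eps ~ N(0, sigma_resid^2)`.
Baseline parity group is 1; the sex indicator is 1 for female pups (female
pups wean lighter, pi4 < 0). Variants: `null`, `linear` (+pi5·L_w),
`quadratic` (+pi6·L_w²), `parity` (replaces the parity main effects with
L_w-by-parity interactions — not nested in the null, so it is compared by
AIC only), `cohort` (per-cohort offsets, baseline = earliest cohort).

**Fitting.** ML is the default so likelihood-ratio tests on fixed effects
are valid; REML is available by flag. The deviance is profiled over the
fixed effects and the residual variance, leaving the two log variance
ratios `log(sigma_alpha^2/sigma_resid^2)`, `log(sigma_eta^2/sigma_resid^2)`,
optimized by bounded L-BFGS-B from three fixed starting points (log-ratios
−2, 0, 1.5; bounds ±(14, 8) cover the numerically degenerate corners).
W-solves use the Woodbury identity, so one objective evaluation costs one
Cholesky of a (n_females + n_years)² matrix. Fits are deterministic given
the data. Fixed-effect covariance is the usual GLS expression at the fitted
variance parameters. The fit agrees with lme4 ML on simulated data to
~1e-4 (the residual gap is the reference optimizer's convergence error, as
the log-likelihoods agree to <1e-4 with ours equal or higher).

**Derived quantities.** `variance_partition` reports each component's share
of `sigma_alpha^2 + sigma_eta^2 + sigma_resid^2` (on the variance scale —
under the default generating values the individual share is ≈ 41% and the
year share ≈ 11%). `predict_mass_spread` evaluates the expected
weaning-mass difference between two maternal L_w values (default 90 vs 132
cm) with a normal-approximation interval from the fixed-effect covariance;
for the linear variant this is exactly `pi5 * (z(132) − z(90))`. Note the
spread depends on the standardization constants: with an L_w sd near 4.3 cm
the default generating effect of 1.07 kg/sd spans roughly 10 kg across the
90–132 cm range.

## Multistate mark–recapture model (breeding rate)

After recruitment a female occupies latent states F (first-time breeder;
entry state only), B (breeder) or N (nonbreeder). The probability of
transitioning from previous state k into B in season t is

    logit psi_{i,t}^{kB} = mu + lambda1*age_z + lambda2*age2_z + lambda3[k]
                           + (L_w terms) + beta_i + theta_t

with sum-to-zero previous-state effects `lambda3` (F, B, N), individual
effects `beta_i ~ N(0, sigma_beta^2)` and season effects
`theta_t ~ N(0, sigma_theta^2)`. Observation: breeders are sighted with
probability p (constant; a single p is what the reference analyses report),
nonbreeders are never sighted, and the recruitment sighting is conditioned
out. There is no death or emigration state: adult survival in this system
is ≈ 0.99 and breeding-colony site fidelity is extremely high, so histories
are simply truncated at the study's end. A cost of reproduction appears as
`psi_BB < psi_NB` — breeding last year lowering this year's breeding odds.

The printed form of this model family sometimes carries an occasion-level
term `omega_{i,t}`; a logistic model has no residual, and no variance for
it is reported, so fitting omits it. The simulator can optionally inject
logit-normal overdispersion (`sigma_omega`, default 0) for robustness
studies; fitting such data with the standard model is then deliberately
misspecified. Marginalizing omega in the likelihood would need per-cell
quadrature and is out of scope.

**Likelihood.** The marginal probability of a post-recruitment sighting
vector sums over latent sequences by a forward recursion with emissions
P(y=1|B) = p, P(y=0|B) = 1−p, P(y=1|N) = 0, P(y=0|N) = 1. Parity (1/2/3+)
is carried inside the latent state space (6 states = {B,N} × parity group),
so the L_w-by-parity variant's covariate is the latent parity, exactly.
For the other variants parity has no effect and the recursion reduces to the
2-state computation. A brute-force enumeration over all 2^m latent
sequences (m ≤ 12) is kept as a verification oracle; forward ≡ brute force
to 1e-10 is asserted over 1,000 random cases in the test suite, and with
p = 1 the likelihood collapses to the closed-form Markov-chain product.

**Priors** (defaults mirroring the analysis protocol): all logit-scale
fixed effects N(0, 1000) (variance), `sigma_beta`, `sigma_theta` ~
Uniform(0, 10), p ~ Uniform(0, 1). All are configurable (`PriorConfig`),
which the calibration tests use.

**Posterior sampling.** A Gibbs scheme alternates:

1. latent states | parameters — exact forward-filter backward-sampler;
2. p | states — conjugate Beta(1 + sighted breeders, 1 + missed breeders),
   rejection-truncated to the prior bounds;
3. fixed-effect block — adaptive Metropolis (Haario-style covariance
   adaptation during burn-in, frozen afterwards), several attempts per
   sweep;
4. translation moves along weakly identified directions: (mu, theta−),
   (mu, beta−) and (lambda5, beta − lambda5·L_w) are likelihood-invariant
   maps accepted on the prior ratio alone, and (lambda1, lambda2) vs a
   year trend in theta is proposed along the occasion-mean age columns and
   accepted with a full likelihood evaluation. These directions are nearly
   flat because age is almost collinear with calendar year when cohorts
   span only five years, and a covariate plus free random effects can trade
   off; without the moves those coordinates mix an order of magnitude
   slower.
5. joint rescalings (sigma, effects) → (sigma·e^d, effects·e^d) for both
   random-effect blocks — the ancillarity–sufficiency move that cures the
   funnel at small sigma. The log-Jacobian is (n+1)d against a prior change
   of −nd, so the acceptance ratio is the likelihood ratio times e^d.
6. parallel single-site Metropolis for all beta_i and all theta_t (valid
   because, given the latent states, the Bernoulli transition cells
   factorize over females and over target occasions), then exact
   conditional (Gibbs) draws of the sigmas: under the uniform-on-sd
   prior, 1/sigma^2 | effects is Gamma((n-1)/2, rate = sum(effects^2)/2)
   truncated to the prior bounds (rejection-sampled, with a random-walk
   fallback under extreme truncation). A random-walk sigma update was
   found too sticky to traverse toward sigma ~ 0 when the data carry no
   heterogeneity, which inflated the conditional-scale coefficients.

Scalar proposal scales adapt by Robbins–Monro toward 0.44 acceptance (0.25
for the block) during burn-in only, preserving the stationary distribution
after it. Each chain initializes the latent states at the sighting vector,
the intercept near the logit of the raw resight rate, and jitters all
starting values so chains start apart. Hot loops are numba-compiled; a
readable numpy forward recursion is the tested reference.

**Correctness evidence** (all in the test suite): forward ≡ brute force;
with no data the sampler reproduces its priors (KS on lambda5 vs N(0,1000),
p uniform); simulation-based calibration — generating parameters drawn from
the fitting priors, rank of truth within the posterior uniform (chi-square,
alpha 0.01, 50 replicates) for lambda5, p and sigma_beta; parameter
recovery at the default generating values. SBC cannot run under the
analysis priors themselves (N(0,1000) on a logit scale yields degenerate
all-or-nothing colonies), so it runs under a narrowed prior configuration
used identically for generation and fitting; this validates the sampler
machinery, not the diffuse-prior posterior geometry. SBC also conditions on
the generating model, so it fits unfiltered histories; the analysis
pipeline's single-season filter is a (mild, deliberate) selection that the
reference analyses share.

**Convergence.** Split-chain R-hat (implemented directly; cross-checked
against arviz's split method) for every scalar parameter; a fit is flagged,
not failed, when any exceeds 1.05. The default protocol is 3 chains,
10,000 burn-in, 100,000 iterations keeping every 100th (3,000 retained);
tests and the acceptance script use scaled-down profiles stated in place
(typically 3 × (400–800 burn, 1,200–2,400 kept, thin 3)).

**Identifiability caveat.** With cohorts spanning 1998–2002 observed over
2002–2020, a female's age is nearly a linear function of calendar year, so
`lambda1`/`lambda2` are informed mainly by the five-cohort contrast and
their marginal posteriors are wide and strongly correlated with the year
effects. Point recovery of the age coefficients on a single synthetic
dataset is therefore poor even when the sampler is exactly calibrated (the
SBC ranks for lambda1 are uniform). The L_w effect, detection and the
transition rates — the quantities of scientific interest — are unaffected.

## Model comparison and posterior summaries

* **WAIC** (smaller is better): `lppd_i = log mean_s exp(loglik_{s,i})`,
  `p_waic_i = Var_s loglik_{s,i}` (sample variance, ddof 1), `waic =
  −2(lppd − p_waic)`. The pointwise unit defaults to one female's whole
  post-recruitment history, because within-female occasions are dependent
  through `beta_i`; a per-occasion option (one term per forward-recursion
  normalizer) is provided for sensitivity. Cross-checked against arviz up
  to its ddof-0 variance convention.
* **LRT / AIC** for the provisioning family (`AIC = 2k − 2 loglik`, k =
  fixed effects + 3 variance components).
* **Transition rates**: posterior mean, sd and equal-tailed 2.5/50/97.5%
  quantiles of psi_FB, psi_BB, psi_NB at a stated covariate point (default:
  standardized age 0, standardized L_w 0, random effects 0 — the analysis
  sample's means; any published spread evaluated under unknown constants is
  re-derived under these documented ones instead).
* **Cost contrast**: draw-wise psi_BB − psi_NB at the same covariate point,
  with mean, 95% CRI and P(contrast < 0).

## Synthetic colonies

`simulate_colony` emulates the study design: 363 females from cohorts
1998–2002 (equal probabilities), L_w truncated-normal per cohort (sd 4.28
cm, bounds [90, 132]; the 2002 cohort mean is set 2 cm above the others so
the pooled mean is 112.7 cm and a cohort effect exists to detect);
recruitment ages 4–8 with probabilities (0.025, 0.314, 0.245, 0.286,
0.130) — the first three match the reported fractions, the age-7 mass makes
P(recruit ≤ 7) = 0.87 and the remainder sits at 8 (the tail shape beyond
the reported categories is a config choice); 19 seasons (2002–2020 analog).
Latent breeding follows the transition model above; sightings are
Bernoulli(p) for breeders; every *sighted* breeding occasion (including
recruitment) yields one pup with Bernoulli(0.5) sex (sex ratio not reported;
even is the default) and mass from the provisioning model. Latent states
are returned for truth-checking only.

Default generating values are the reported estimates: transition
lambda1 = 0.385, lambda2 = −0.355, lambda5 = 0.549, p = 0.975,
sigma_beta² = 0.895, sigma_theta² = 1.310, with mu and lambda3 backed out
of the transition rates (psi_FB, psi_BB, psi_NB) = (0.779, 0.861, 0.878);
mass intercept 49.22, pi1 = 14.46, pi2 = −11.88, pi3 = (4.01, 6.23),
pi4 = −2.26, pi5 = 1.07, sigma_ID² = 4.67, sigma_year² = 1.29,
sigma_resid² = 5.45 (kg²). The printed dispersion parameters are
interpreted as **variances** (their symbols are squared and only this
reading reproduces the ≈41% individual / ≈11% year variance partition);
generating standard deviations are their square roots. An optional
`annual_survival` thinning (default 1.0, i.e. off) exists for robustness
studies only — the fitted model has no death state.

**What the simulator does not emulate:** brand misreads and other
identification error; density dependence or environmental covariate series;
pup survival to recruitment (the sample is conditioned on recruitment from
the start); heterogeneous detection (skittish nonbreeders are simply
undetectable, as in the model); mortality. Passing recovery tests therefore
shows the estimators are correct and calibrated *under the model's own
assumptions at the study's scale* — not that the model is adequate for any
particular real colony.

## Numerical choices and degenerate inputs

* Forward recursion in linear space with per-step normalization; an
  impossible observation (e.g. a sighting when p = 1 forces an impossible
  path) returns −inf rather than raising.
* Logistic terms use the stable log1p/exp formulations throughout.
* Histories of length 1 after recruitment have log-likelihood 0 (the
  conditioned event); females recruiting at the final occasion contribute
  nothing and are handled (though the study filter removes them).
* LMM: zero variance ratios are reachable (bounds extend to e^−14); the
  all-zero variance partition raises; singular designs (an absent factor
  level) raise rather than silently dropping columns.
* Detection draws are clamped away from exactly 0/1 to keep emissions
  finite; the truncated-Beta rejection loop is capped (the cap is
  unreachable in practice because the posterior concentrates inside the
  bounds).
* Row-duplication is *not* an invariance of mixed models (duplicated rows
  share random-effect levels, rescaling the residual-to-RE variance ratio
  and re-weighting clusters), so the suite tests row-order/relabel
  invariance and the exact profile check instead.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `detection_p` | P(sight a breeder in ≥1 census) | 0.975 | reported posterior mean |
| `lambda5` | L_w effect on breeding (logit per sd) | 0.549 | reported posterior mean |
| `pi5` | L_w effect on pup mass (kg per sd) | 1.07 | reported estimate |
| `sigma_beta`, `sigma_theta` | individual / year sd, logit | √0.895, √1.310 | reported variances |
| `sigma_alpha`, `sigma_eta`, `sigma_resid` | mass variance components (kg) | √4.67, √1.29, √5.45 | reported variances |
| `n_females`, `n_occasions` | study scale | 363, 19 | study sample |
| MCMC protocol | chains/burn/iters/thin | 3 / 10⁴ / 10⁵ / 100 | analysis protocol; tests scale down |
| R-hat flag | convergence threshold | 1.05 | operationalizes "close to 1.00" |

## Known limitations

* No death/emigration state; unsuitable for colonies where adult mortality
  or permanent emigration is non-negligible within the study window.
* Detection is constant across seasons and females.
* The occasion-level overdispersion term can be simulated but not fitted.
* The age coefficients are weakly identified by design (see caveat above).
* The single-season filter induces mild selection that the likelihood does
  not model; at the default detection and breeding rates the effect is
  negligible (typically zero to a handful of females).
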
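"""Mixed-effects multistate mark-recapture model of breeding rate.

A female's reproductive history after recruitment is a latent Markov chain
over breeding states: F (first-time breeder, entry state at recruitment),
B (breeder) and N (nonbreeder), observed through imperfect detection.
Breeders are sighted with probability ``p``; nonbreeders are never sighted.
The probability of transitioning from previous state k into B is a
mixed-effects logistic regression:

    logit psi_{i,t}^{kB} = mu + lambda1*age_z + lambda2*age2_z + lambda3[k]
                           + (weaning-length terms, variant dependent)
                           + beta_i + theta_t

with sum-to-zero previous-state effects lambda3, individual random effects
beta_i ~ N(0, sigma_beta^2) and year effects theta_t ~ N(0, sigma_theta^2).
Age, age^2, L_w and L_w^2 each enter as separately z-scored columns.

The exact marginal likelihood of a sighting vector integrates over the
latent {B, N} sequence by a forward recursion; parity (1, 2, 3+) is carried
in the latent state space so the L_w-by-parity variant stays exact. A
brute-force enumeration over all latent sequences is kept as an oracle.

Fitting is Bayesian MCMC: a forward-filter backward-sampler draws the latent
states exactly, after which detection p has a conjugate Beta update, the
fixed-effect block uses an adaptive Metropolis step, and the random effects
use parallel single-site Metropolis steps (valid because, given the latent
states, the Bernoulli transition likelihood factorizes over females and
over occasions). Hot loops are numba-compiled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .data import EncounterHistory, Standardizer, fit_standardizer

logger = logging.getLogger("sealrep")

__all__ = [
    "STATES",
    "VARIANTS",
    "TransitionParams",
    "FemaleCovariates",
    "MultistateDesign",
    "McmcConfig",
    "PriorConfig",
    "PosteriorSamples",
    "breeding_probability",
    "forward_loglik",
    "brute_force_loglik",
    "build_design",
    "fit_multistate",
    "transition_summary",
]

STATES = ("F", "B", "N")
VARIANTS = ("null", "linear", "quadratic", "parity", "cohort")
_VARIANT_CODE = {v: i for i, v in enumerate(VARIANTS)}

#: maximum post-recruitment length accepted by the brute-force oracle
BRUTE_FORCE_MAX_LEN = 12


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class TransitionParams:
    """All parameters of the transition model (logit scale).

    ``lambda3`` holds the previous-state effects in the order (F, B, N) and
    must sum to zero. ``lambda5``/``lambda6`` are the weaning-length terms
    whose meaning depends on the model variant; ``lambda_cohort`` are
    per-cohort offsets (baseline cohort first, fixed at 0).
    """

    mu: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lambda5: float = 0.0
    lambda6: float = 0.0
    lambda_cohort: np.ndarray | None = None
    beta: np.ndarray | None = None
    theta: np.ndarray | None = None
    sigma_beta: float = 0.0
    sigma_theta: float = 0.0
    detection_p: float = 1.0

    def __post_init__(self) -> None:
        self.lambda3 = np.asarray(self.lambda3, dtype=float)
        if self.lambda3.shape != (3,):
            raise ValueError("lambda3 must have 3 entries, order (F, B, N)")
        if abs(self.lambda3.sum()) > 1e-12:
            raise ValueError("lambda3 must sum to zero")
        if self.sigma_beta < 0 or self.sigma_theta < 0:
            raise ValueError("random-effect sds must be >= 0")
        if not (0.0 <= self.detection_p <= 1.0):
            raise ValueError("detection_p must be in [0, 1]")

    @classmethod
    def from_transition_rates(
        cls, psi_FB: float, psi_BB: float, psi_NB: float, **kwargs
    ) -> "TransitionParams":
        """Back out (mu, lambda3) from the three transition rates at the
        covariate reference point (all standardized covariates 0, random
        effects 0)."""
        logits = np.array([_logit(psi_FB), _logit(psi_BB), _logit(psi_NB)])
        mu = float(logits.mean())
        return cls(mu=mu, lambda3=logits - mu, **kwargs)


@dataclass
class FemaleCovariates:
    """Per-female covariates on the standardized scale used by the model."""

    std_age: np.ndarray  # standardized age, one entry per occasion
    std_age_sq: np.ndarray  # standardized age^2 (its own z-score column)
    std_lw: float = 0.0
    std_lw_sq: float = 0.0
    cohort_index: int = 0


def _check_variant(variant: str) -> int:
    if variant not in _VARIANT_CODE:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return _VARIANT_CODE[variant]


def _variant_extra(
    params: TransitionParams,
    variant: str,
    std_lw: float,
    std_lw_sq: float,
    parity_group: int,
    cohort_index: int,
) -> float:
    if variant == "null":
        return 0.0
    extra = params.lambda5 * std_lw
    if variant == "quadratic":
        extra += params.lambda6 * std_lw_sq
    elif variant == "parity":
        if parity_group == 1:
            extra += params.lambda6 * std_lw
    elif variant == "cohort":
        if cohort_index > 0:
            if params.lambda_cohort is None:
                raise ValueError("cohort variant needs lambda_cohort offsets")
            extra += params.lambda_cohort[cohort_index - 1]
    return extra


def breeding_probability(
    params: TransitionParams,
    prev_state: str,
    std_age: float,
    std_lw: float,
    *,
    std_age_sq: float | None = None,
    std_lw_sq: float | None = None,
    parity_group: int = 1,
    cohort_index: int = 0,
    female_effect: float = 0.0,
    occasion_effect: float = 0.0,
    variant: str = "linear",
) -> float:
    """Probability of breeding given previous state and covariates.

    Inverse-logit of the variant's linear predictor. ``std_age_sq`` and
    ``std_lw_sq`` default to the squares of the standardized values; pass
    separately standardized columns for full control.
    """
    _check_variant(variant)
    if prev_state not in STATES:
        raise ValueError(f"unknown previous state {prev_state!r}")
    if std_age_sq is None:
        std_age_sq = std_age**2
    if std_lw_sq is None:
        std_lw_sq = std_lw**2
    lp = (
        params.mu
        + params.lambda1 * std_age
        + params.lambda2 * std_age_sq
        + params.lambda3[STATES.index(prev_state)]
        + female_effect
        + occasion_effect
        + _variant_extra(params, variant, std_lw, std_lw_sq, parity_group, cohort_index)
    )
    if not np.isfinite(lp):
        raise ValueError("non-finite linear predictor")
    return 1.0 / (1.0 + math.exp(-lp))


# ---------------------------------------------------------------------------
# exact marginal likelihood (numpy reference implementation)
# ---------------------------------------------------------------------------
# Latent state space: s = b*3 + (g-1) with b in {0=N, 1=B} and parity group
# g in {1, 2, 3}. At recruitment the female is in F with her first pup, so
# the chain starts at (b=1, g=1) with probability 1; the recruitment sighting
# is conditioned out. The F previous-state effect applies only to the first
# transition after recruitment.


def _psi_prev_states(
    params: TransitionParams,
    variant: str,
    cov: FemaleCovariates,
    t: int,
    first_transition: bool,
    beta_i: float,
    theta_t: float,
) -> np.ndarray:
    """Breeding probability for each of the 6 previous latent states at t."""
    psi = np.empty(6)
    for s in range(6):
        b_prev, g = divmod(s, 3)
        g += 1
        prev = "F" if first_transition else ("B" if b_prev == 1 else "N")
        psi[s] = breeding_probability(
            params,
            prev,
            float(cov.std_age[t]),
            cov.std_lw,
            std_age_sq=float(cov.std_age_sq[t]),
            std_lw_sq=cov.std_lw_sq,
            parity_group=g,
            cohort_index=cov.cohort_index,
            female_effect=beta_i,
            occasion_effect=theta_t,
            variant=variant,
        )
    return psi


def forward_loglik(
    history: EncounterHistory,
    covariates: FemaleCovariates,
    params: TransitionParams,
    variant: str = "null",
    *,
    female_index: int = 0,
) -> float:
    """Exact marginal log-likelihood of one post-recruitment sighting vector.

    Sums over latent {B, N} (x parity) sequences by the forward recursion,
    conditioning on state F with probability 1 at the recruitment occasion.
    Emissions: P(y=1 | B) = p, P(y=0 | B) = 1 - p, P(y=1 | N) = 0,
    P(y=0 | N) = 1.
    """
    _check_variant(variant)
    y = np.asarray(history.sightings)
    r = history.recruit_occasion
    T = y.size
    if (y[:r] == 1).any():  # pragma: no cover - recruit_occasion is first 1
        raise ValueError("sighting before recruitment")
    p = params.detection_p
    beta_i = 0.0 if params.beta is None else float(params.beta[female_index])
    theta = np.zeros(T) if params.theta is None else np.asarray(params.theta, dtype=float)

    alpha = np.zeros(6)
    alpha[3 + 0] = 1.0  # (b=1, g=1) at recruitment
    ll = 0.0
    for t in range(r + 1, T):
        psi = _psi_prev_states(params, variant, covariates, t, t == r + 1, beta_i, theta[t])
        new = np.zeros(6)
        for s in range(6):
            a = alpha[s]
            if a == 0.0:
                continue
            b_prev, g = divmod(s, 3)
            g += 1
            g_up = min(g + 1, 3)
            new[3 + (g_up - 1)] += a * psi[s]
            new[(g - 1)] += a * (1.0 - psi[s])
        if y[t] == 1:
            new[:3] = 0.0
            new[3:] *= p
        else:
            new[3:] *= 1.0 - p
        c = new.sum()
        if c <= 0.0:
            return -np.inf
        ll += math.log(c)
        alpha = new / c
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood")
    return ll


def brute_force_loglik(
    history: EncounterHistory,
    covariates: FemaleCovariates,
    params: TransitionParams,
    variant: str = "null",
    *,
    female_index: int = 0,
) -> float:
    """Verification oracle: log sum over all 2^m latent {B, N} sequences of
    P(states) * P(sightings | states). Post-recruitment length capped at
    ``BRUTE_FORCE_MAX_LEN``."""
    _check_variant(variant)
    y = np.asarray(history.sightings)
    r = history.recruit_occasion
    T = y.size
    m = T - 1 - r
    if m > BRUTE_FORCE_MAX_LEN:
        raise ValueError(f"history too long for brute force ({m} > {BRUTE_FORCE_MAX_LEN})")
    if m == 0:
        return 0.0
    p = params.detection_p
    beta_i = 0.0 if params.beta is None else float(params.beta[female_index])
    theta = np.zeros(T) if params.theta is None else np.asarray(params.theta, dtype=float)

    total = 0.0
    for code in range(2**m):
        bits = [(code >> j) & 1 for j in range(m)]  # latent b at r+1 .. T-1
        prob = 1.0
        births = 1  # recruitment birth
        prev_b = 1
        for j, b_now in enumerate(bits):
            t = r + 1 + j
            first = j == 0
            g_prev = min(births, 3)
            prev = "F" if first else ("B" if prev_b == 1 else "N")
            psi = breeding_probability(
                params,
                prev,
                float(covariates.std_age[t]),
                covariates.std_lw,
                std_age_sq=float(covariates.std_age_sq[t]),
                std_lw_sq=covariates.std_lw_sq,
                parity_group=g_prev,
                cohort_index=covariates.cohort_index,
                female_effect=beta_i,
                occasion_effect=float(theta[t]),
                variant=variant,
            )
            prob *= psi if b_now == 1 else (1.0 - psi)
            if y[t] == 1:
                prob *= p if b_now == 1 else 0.0
            else:
                prob *= (1.0 - p) if b_now == 1 else 1.0
            if prob == 0.0:
                break
            births += b_now
            prev_b = b_now
        total += prob
    if total <= 0.0:
        return -np.inf
    return math.log(total)


# ---------------------------------------------------------------------------
# design: fitting-ready arrays built from a filtered colony
# ---------------------------------------------------------------------------


@dataclass
class MultistateDesign:
    """Arrays consumed by the likelihood kernels and the sampler."""

    female_ids: list[str]
    y: np.ndarray  # (n, T) int8 sightings
    recruit: np.ndarray  # (n,) int64 recruit occasion
    z_age: np.ndarray  # (n, T) standardized age
    z_age_sq: np.ndarray  # (n, T) standardized age^2
    z_lw: np.ndarray  # (n,) standardized weaning length
    z_lw_sq: np.ndarray  # (n,) standardized weaning length^2
    cohort_index: np.ndarray  # (n,) int64, baseline cohort = 0
    n_cohorts: int
    years: np.ndarray
    standardizers: dict[str, Standardizer]

    @property
    def n_females(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def covariates(self, i: int) -> FemaleCovariates:
        return FemaleCovariates(
            std_age=self.z_age[i],
            std_age_sq=self.z_age_sq[i],
            std_lw=float(self.z_lw[i]),
            std_lw_sq=float(self.z_lw_sq[i]),
            cohort_index=int(self.cohort_index[i]),
        )


def build_design(
    histories: Sequence[EncounterHistory],
    female_table,
    *,
    standardizers: dict[str, Standardizer] | None = None,
) -> MultistateDesign:
    """Assemble fitting arrays from filtered histories and the female table.

    Age, age^2, L_w and L_w^2 are z-scored as separate columns. By default
    the constants come from the analysis sample (ages pooled over all
    post-recruitment female-occasions); pass ``standardizers`` (e.g. from a
    simulation manifest) to standardize with externally fixed constants.
    """
    females = female_table.set_index("female_id")
    ids = [h.female_id for h in histories]
    missing = [fid for fid in ids if fid not in females.index]
    if missing:
        raise ValueError(f"females missing from covariate table: {missing[:5]}")
    T = histories[0].sightings.size
    years = histories[0].occasion_labels
    n = len(histories)
    y = np.zeros((n, T), dtype=np.int8)
    recruit = np.zeros(n, dtype=np.int64)
    age = np.zeros((n, T))
    lw = np.zeros(n)
    cohorts = np.zeros(n, dtype=np.int64)
    for i, h in enumerate(histories):
        y[i] = h.sightings
        recruit[i] = h.recruit_occasion
        cohort = int(females.loc[h.female_id, "cohort"])
        cohorts[i] = cohort
        lw[i] = float(females.loc[h.female_id, "weaning_length_cm"])
        age[i] = years - cohort

    post = np.arange(T)[None, :] >= recruit[:, None]
    if standardizers is None:
        standardizers = {
            "age": fit_standardizer(age[post]),
            "age_sq": fit_standardizer(age[post] ** 2),
            "lw": fit_standardizer(lw),
            "lw_sq": fit_standardizer(lw**2),
        }
    z_age = standardizers["age"].transform(age)
    z_age_sq = standardizers["age_sq"].transform(age**2)
    z_lw = standardizers["lw"].transform(lw)
    z_lw_sq = standardizers["lw_sq"].transform(lw**2)

    uniq = np.unique(cohorts)
    cohort_index = np.searchsorted(uniq, cohorts)
    return MultistateDesign(
        female_ids=ids,
        y=y,
        recruit=recruit,
        z_age=z_age,
        z_age_sq=z_age_sq,
        z_lw=z_lw,
        z_lw_sq=z_lw_sq,
        cohort_index=cohort_index,
        n_cohorts=len(uniq),
        years=np.asarray(years),
        standardizers=standardizers,
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------
# phi layout: [mu, lambda1, lambda2, lambda3_F, lambda3_B] + variant extras
#   linear:    [lambda5]
#   quadratic: [lambda5, lambda6]
#   parity:    [lambda5, lambda6]           (lambda6 on z_lw * I(parity == 1))
#   cohort:    [lambda5, c_1 .. c_{K-1}]    (baseline cohort offset = 0)


def _n_phi(variant_code: int, n_cohorts: int) -> int:
    # cohort variant: lambda5 plus (n_cohorts - 1) offsets
    return 5 + {0: 0, 1: 1, 2: 2, 3: 2, 4: n_cohorts}[variant_code]


@njit(cache=False)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=False)
def _lp_cell(phi, variant, zage, zage2, zlw, zlw2, coh, beta_i, theta_t, k, g):
    """Linear predictor for one transition cell; k: 0=F, 1=B, 2=N."""
    lp = phi[0] + phi[1] * zage + phi[2] * zage2 + beta_i + theta_t
    if k == 0:
        lp += phi[3]
    elif k == 1:
        lp += phi[4]
    else:
        lp -= phi[3] + phi[4]
    if variant >= 1:
        lp += phi[5] * zlw
    if variant == 2:
        lp += phi[6] * zlw2
    elif variant == 3:
        if g == 1:
            lp += phi[6] * zlw
    elif variant == 4:
        if coh > 0:
            lp += phi[5 + coh]
    return lp


@njit(cache=False)
def _bern_ll(lp, b):
    """log Bernoulli(b | sigmoid(lp)), numerically stable."""
    if lp >= 0.0:
        lse = lp + math.log1p(math.exp(-lp))
    else:
        lse = math.log1p(math.exp(lp))
    if b == 1:
        return lp - lse
    return -lse


@njit(cache=False)
def _forward_logc(
    y, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort, variant, phi, beta, theta, p, logc
):
    """Forward recursion for every female; per-occasion log normalizers into
    ``logc`` (zeros where undefined). Returns nothing; per-female marginal
    log-likelihood is logc.sum(axis=1)."""
    n, T = y.shape
    alpha = np.zeros(6)
    new = np.zeros(6)
    for i in range(n):
        r = recruit[i]
        for t in range(T):
            logc[i, t] = 0.0
        if r >= T - 1:
            continue
        for s in range(6):
            alpha[s] = 0.0
        alpha[3] = 1.0
        for t in range(r + 1, T):
            for s in range(6):
                new[s] = 0.0
            for s in range(6):
                a = alpha[s]
                if a <= 0.0:
                    continue
                b_prev = s // 3
                g = s % 3 + 1
                k = 0 if t == r + 1 else (1 if b_prev == 1 else 2)
                lp = _lp_cell(
                    phi, variant, z_age[i, t], z_age_sq[i, t],
                    z_lw[i], z_lw_sq[i], cohort[i], beta[i], theta[t], k, g,
                )
                ps = _sigmoid(lp)
                g_up = g + 1 if g < 3 else 3
                new[3 + g_up - 1] += a * ps
                new[g - 1] += a * (1.0 - ps)
            if y[i, t] == 1:
                for gg in range(3):
                    new[gg] = 0.0
                    new[3 + gg] *= p
            else:
                for gg in range(3):
                    new[3 + gg] *= 1.0 - p
            c = 0.0
            for s in range(6):
                c += new[s]
            if c <= 0.0:
                logc[i, t] = -np.inf
                break
            logc[i, t] = math.log(c)
            for s in range(6):
                alpha[s] = new[s] / c


@njit(cache=False)
def _ffbs(
    y, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort, variant, phi, beta, theta, p, b_out
):
    """Sample the latent breeding indicators exactly from their conditional
    distribution given data and parameters (forward filter, backward sample)."""
    n, T = y.shape
    alpha = np.zeros((T, 6))
    psis = np.zeros((T, 6))
    for i in range(n):
        r = recruit[i]
        for t in range(T):
            b_out[i, t] = 0
        b_out[i, r] = 1
        if r >= T - 1:
            continue
        for t in range(T):
            for s in range(6):
                alpha[t, s] = 0.0
        alpha[r, 3] = 1.0
        for t in range(r + 1, T):
            for s in range(6):
                a = alpha[t - 1, s]
                if a <= 0.0:
                    continue
                b_prev = s // 3
                g = s % 3 + 1
                k = 0 if t == r + 1 else (1 if b_prev == 1 else 2)
                lp = _lp_cell(
                    phi, variant, z_age[i, t], z_age_sq[i, t],
                    z_lw[i], z_lw_sq[i], cohort[i], beta[i], theta[t], k, g,
                )
                ps = _sigmoid(lp)
                psis[t, s] = ps
                g_up = g + 1 if g < 3 else 3
                alpha[t, 3 + g_up - 1] += a * ps
                alpha[t, g - 1] += a * (1.0 - ps)
            if y[i, t] == 1:
                for gg in range(3):
                    alpha[t, gg] = 0.0
                    alpha[t, 3 + gg] *= p
            else:
                for gg in range(3):
                    alpha[t, 3 + gg] *= 1.0 - p
            c = 0.0
            for s in range(6):
                c += alpha[t, s]
            for s in range(6):
                alpha[t, s] /= c
        # backward sampling
        u = np.random.random()
        acc = 0.0
        s_cur = 5
        for s in range(6):
            acc += alpha[T - 1, s]
            if u <= acc:
                s_cur = s
                break
        b_out[i, T - 1] = s_cur // 3
        for t in range(T - 1, r + 1, -1):
            bt = s_cur // 3
            gt = s_cur % 3 + 1
            wsum = 0.0
            w = np.zeros(6)
            for sp in range(6):
                a = alpha[t - 1, sp]
                if a <= 0.0:
                    continue
                gp = sp % 3 + 1
                if bt == 1:
                    gup = gp + 1 if gp < 3 else 3
                    if gup == gt:
                        w[sp] = a * psis[t, sp]
                else:
                    if gp == gt:
                        w[sp] = a * (1.0 - psis[t, sp])
                wsum += w[sp]
            u = np.random.random() * wsum
            acc = 0.0
            s_cur = 5
            for sp in range(6):
                acc += w[sp]
                if u <= acc and w[sp] > 0.0:
                    s_cur = sp
                    break
            b_out[i, t - 1] = s_cur // 3


@njit(cache=False)
def _cells_ll(
    b, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort, variant, phi, beta, theta,
    ll_i, ll_t,
):
    """Transition-cell log-likelihood given latent states, accumulated per
    female (ll_i) and per target occasion (ll_t). Total = ll_i.sum()."""
    n, T = b.shape
    for i in range(n):
        ll_i[i] = 0.0
    for t in range(T):
        ll_t[t] = 0.0
    for i in range(n):
        r = recruit[i]
        g = 1
        for t in range(r + 1, T):
            k = 0 if t == r + 1 else (1 if b[i, t - 1] == 1 else 2)
            lp = _lp_cell(
                phi, variant, z_age[i, t], z_age_sq[i, t],
                z_lw[i], z_lw_sq[i], cohort[i], beta[i], theta[t], k, g,
            )
            ll = _bern_ll(lp, b[i, t])
            ll_i[i] += ll
            ll_t[t] += ll
            if b[i, t] == 1 and g < 3:
                g += 1


@njit(cache=False)
def _draw_sigma(cur, ssq, m, lo, hi, rw_step):
    """Draw a random-effect sd from its conditional given the m effects.

    Under a Uniform(lo, hi) prior on the sd, x = 1/sigma^2 | effects follows
    Gamma((m-1)/2, rate ssq/2) truncated to the bounds; sampled by rejection
    (whose success probability does not depend on the current sd, so mixing
    in the random-walk fallback when truncation is extreme stays valid)."""
    if m >= 2 and ssq > 1e-280:
        shape = (m - 1) / 2.0
        scale = 2.0 / ssq
        for _try in range(200):
            x = np.random.gamma(shape, scale)
            if x > 0.0:
                s = 1.0 / math.sqrt(x)
                if lo < s < hi:
                    return s
    cand = cur + rw_step * np.random.normal()
    if lo < cand < hi:
        dpost = -m * (math.log(cand) - math.log(cur)) - ssq / 2.0 * (
            1.0 / cand**2 - 1.0 / cur**2
        )
        if math.log(np.random.random() + 1e-300) < dpost:
            return cand
    return cur


@njit(cache=False)
def _run_chain(
    seed,
    y, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
    variant, n_phi,
    lambda_sd, sb_lo, sb_hi, st_lo, st_hi, p_lo, p_hi,
    n_burn, n_keep, thin,
):
    """One MCMC chain. Returns (phi, beta, theta, sigma_beta, sigma_theta,
    p, loglik_female) draws, each with n_keep rows.

    Besides the standard component updates, the sweep includes translation
    moves along weakly identified directions: the intercept trades off
    against the means of theta and beta (likelihood-invariant, prior-only
    acceptance), lambda5 against beta (the L_w column can be absorbed by the
    individual effects), and the age coefficients against a year trend in
    theta (age is nearly collinear with calendar year when cohorts span only
    a few years). Without these moves those directions mix very slowly."""
    np.random.seed(seed)
    n, T = y.shape

    # --- initial values (jittered so chains start apart) ---
    n_cells = 0
    n_sight = 0
    for i in range(n):
        for t in range(recruit[i] + 1, T):
            n_cells += 1
            n_sight += y[i, t]
    rate = (n_sight + 1.0) / (n_cells + 2.0)
    phi = np.random.normal(0.0, 0.2, n_phi)
    phi[0] += math.log(rate / (1.0 - rate))
    beta = np.zeros(n)
    theta = np.zeros(T)
    sig_b = sb_lo + (sb_hi - sb_lo) * (0.3 + 0.4 * np.random.random())
    sig_t = st_lo + (st_hi - st_lo) * (0.3 + 0.4 * np.random.random())
    p = p_lo + (p_hi - p_lo) * (0.85 + 0.1 * np.random.random())
    b_lat = np.zeros((n, T), dtype=np.int8)
    for i in range(n):
        for t in range(T):
            b_lat[i, t] = y[i, t]
        b_lat[i, recruit[i]] = 1

    # occasion-wise mean age covariates over active cells (for ridge moves)
    abar = np.zeros(T)
    a2bar = np.zeros(T)
    for t in range(T):
        cnt = 0
        for i in range(n):
            if recruit[i] < t:
                abar[t] += z_age[i, t]
                a2bar[t] += z_age_sq[i, t]
                cnt += 1
        if cnt > 0:
            abar[t] /= cnt
            a2bar[t] /= cnt

    # --- adaptation state ---
    ls_phi = math.log(0.3)
    ls_beta = math.log(0.5)
    ls_theta = math.log(0.5)
    ls_sb = math.log(0.3)
    ls_st = math.log(0.3)
    ls_mt = math.log(0.5)   # mu <-> theta translation
    ls_mb = math.log(0.3)   # mu <-> beta translation
    ls_lb = math.log(0.3)   # lambda5 <-> beta translation
    ls_at = math.log(0.2)   # (lambda1, lambda2) <-> theta trend
    ls_rb = math.log(0.3)   # (sigma_beta, beta) joint rescale
    ls_rt = math.log(0.3)   # (sigma_theta, theta) joint rescale
    prop_chol = np.eye(n_phi) * 0.05
    mean_phi = np.zeros(n_phi)
    m2_phi = np.zeros((n_phi, n_phi))
    n_hist = 0

    ll_i = np.zeros(n)
    ll_t = np.zeros(T)
    ll_i_new = np.zeros(n)
    ll_t_new = np.zeros(T)
    logc = np.zeros((n, T))

    phi_out = np.zeros((n_keep, n_phi))
    beta_out = np.zeros((n_keep, n))
    theta_out = np.zeros((n_keep, T))
    sb_out = np.zeros(n_keep)
    st_out = np.zeros(n_keep)
    p_out = np.zeros(n_keep)
    ll_out = np.zeros((n_keep, n))

    kept = 0
    total = n_burn + n_keep * thin
    for sweep in range(total):
        adapting = sweep < n_burn

        # 1. latent states | params (exact conditional draw)
        if n > 0:
            _ffbs(y, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                  variant, phi, beta, theta, p, b_lat)

        # 2. detection p | latent states: conjugate Beta on (p_lo, p_hi)
        k1 = 0
        k0 = 0
        for i in range(n):
            for t in range(recruit[i] + 1, T):
                if b_lat[i, t] == 1:
                    if y[i, t] == 1:
                        k1 += 1
                    else:
                        k0 += 1
        for _try in range(1000):
            cand = np.random.beta(1.0 + k1, 1.0 + k0)
            if p_lo < cand < p_hi:
                p = cand
                break
        if p >= 1.0 - 1e-12:
            p = 1.0 - 1e-12
        if p <= 1e-12:
            p = 1e-12

        # 3. fixed-effect block: adaptive Metropolis, several attempts per
        # sweep (each costs one cell pass; the block carries all the slowly
        # mixing logit-scale contrasts such as the previous-state effects)
        _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                  variant, phi, beta, theta, ll_i, ll_t)
        ll_cur = ll_i.sum()
        for _rep in range(4):
            step = math.exp(ls_phi)
            eps = np.random.normal(0.0, 1.0, n_phi)
            phi_new = phi + step * (prop_chol @ eps)
            _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                      variant, phi_new, beta, theta, ll_i_new, ll_t_new)
            ll_new = ll_i_new.sum()
            dprior = 0.0
            for j in range(n_phi):
                dprior += (phi[j] ** 2 - phi_new[j] ** 2) / (2.0 * lambda_sd**2)
            acc_phi = 0.0
            if math.log(np.random.random() + 1e-300) < ll_new - ll_cur + dprior:
                for j in range(n_phi):
                    phi[j] = phi_new[j]
                for i in range(n):
                    ll_i[i] = ll_i_new[i]
                for t in range(T):
                    ll_t[t] = ll_t_new[t]
                ll_cur = ll_new
                acc_phi = 1.0
            if adapting:
                ls_phi += (acc_phi - 0.25) / (1.0 + sweep) ** 0.6
                n_hist += 1
                for j in range(n_phi):
                    dj = phi[j] - mean_phi[j]
                    mean_phi[j] += dj / n_hist
                    for l in range(n_phi):
                        m2_phi[j, l] += dj * (phi[l] - mean_phi[l])
        if adapting and n_hist > 8 * n_phi and sweep % 50 == 0:
            cov = m2_phi / (n_hist - 1) * (2.38**2 / n_phi)
            for j in range(n_phi):
                cov[j, j] += 1e-8
            prop_chol = np.linalg.cholesky(cov)

        # 4. translation moves along weakly identified directions
        # (i) mu + d, theta - d: likelihood-invariant, prior-only acceptance
        d = math.exp(ls_mt) * np.random.normal()
        dpost = -((phi[0] + d) ** 2 - phi[0] ** 2) / (2.0 * lambda_sd**2)
        for t in range(T):
            dpost -= ((theta[t] - d) ** 2 - theta[t] ** 2) / (2.0 * sig_t**2)
        acc = 0.0
        if math.log(np.random.random() + 1e-300) < dpost:
            phi[0] += d
            for t in range(T):
                theta[t] -= d
            acc = 1.0
        if adapting:
            ls_mt += (acc - 0.44) / (1.0 + sweep) ** 0.6

        # (ii) mu + d, beta - d: likelihood-invariant
        if n > 0:
            d = math.exp(ls_mb) * np.random.normal()
            dpost = -((phi[0] + d) ** 2 - phi[0] ** 2) / (2.0 * lambda_sd**2)
            for i in range(n):
                dpost -= ((beta[i] - d) ** 2 - beta[i] ** 2) / (2.0 * sig_b**2)
            acc = 0.0
            if math.log(np.random.random() + 1e-300) < dpost:
                phi[0] += d
                for i in range(n):
                    beta[i] -= d
                acc = 1.0
            if adapting:
                ls_mb += (acc - 0.44) / (1.0 + sweep) ** 0.6

        # (iii) lambda5 + d, beta_i - d*z_lw_i: likelihood-invariant
        if variant >= 1 and n > 0:
            d = math.exp(ls_lb) * np.random.normal()
            dpost = -((phi[5] + d) ** 2 - phi[5] ** 2) / (2.0 * lambda_sd**2)
            for i in range(n):
                bn = beta[i] - d * z_lw[i]
                dpost -= (bn**2 - beta[i] ** 2) / (2.0 * sig_b**2)
            acc = 0.0
            if math.log(np.random.random() + 1e-300) < dpost:
                phi[5] += d
                for i in range(n):
                    beta[i] -= d * z_lw[i]
                acc = 1.0
            if adapting:
                ls_lb += (acc - 0.44) / (1.0 + sweep) ** 0.6

        # (iv) age coefficients vs a year trend in theta: approximately
        # likelihood-invariant, so accept with a full cell evaluation
        if n > 0:
            d1 = math.exp(ls_at) * np.random.normal()
            d2 = math.exp(ls_at) * np.random.normal()
            phi_new = phi.copy()
            phi_new[1] += d1
            phi_new[2] += d2
            theta_new = theta.copy()
            dpost = (
                -(phi_new[1] ** 2 - phi[1] ** 2) / (2.0 * lambda_sd**2)
                - (phi_new[2] ** 2 - phi[2] ** 2) / (2.0 * lambda_sd**2)
            )
            for t in range(T):
                theta_new[t] = theta[t] - d1 * abar[t] - d2 * a2bar[t]
                dpost -= (theta_new[t] ** 2 - theta[t] ** 2) / (2.0 * sig_t**2)
            _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                      variant, phi_new, beta, theta_new, ll_i_new, ll_t_new)
            dpost += ll_i_new.sum() - ll_i.sum()
            acc = 0.0
            if math.log(np.random.random() + 1e-300) < dpost:
                for j in range(n_phi):
                    phi[j] = phi_new[j]
                for t in range(T):
                    theta[t] = theta_new[t]
                    ll_t[t] = ll_t_new[t]
                for i in range(n):
                    ll_i[i] = ll_i_new[i]
                acc = 1.0
            if adapting:
                ls_at += (acc - 0.44) / (1.0 + sweep) ** 0.6

        # 5. joint rescaling of (sigma, random effects): cures the funnel
        # where small sigma pins the effects at zero. For the map
        # (sigma, u) -> (sigma*e^d, u*e^d) with n effects, the log-Jacobian
        # is (n+1)*d and the Gaussian prior of the effects changes by -n*d,
        # so the acceptance ratio is the likelihood ratio times e^d
        # (within the uniform sd-prior bounds).
        if n > 0:
            d = math.exp(ls_rb) * np.random.normal()
            cand = sig_b * math.exp(d)
            acc = 0.0
            if sb_lo < cand < sb_hi:
                scale = math.exp(d)
                beta_new = beta * scale
                _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                          variant, phi, beta_new, theta, ll_i_new, ll_t_new)
                if math.log(np.random.random() + 1e-300) < ll_i_new.sum() - ll_i.sum() + d:
                    sig_b = cand
                    for i in range(n):
                        beta[i] = beta_new[i]
                        ll_i[i] = ll_i_new[i]
                    for t in range(T):
                        ll_t[t] = ll_t_new[t]
                    acc = 1.0
            if adapting:
                ls_rb += (acc - 0.44) / (1.0 + sweep) ** 0.6

        d = math.exp(ls_rt) * np.random.normal()
        cand = sig_t * math.exp(d)
        acc = 0.0
        if st_lo < cand < st_hi:
            scale = math.exp(d)
            theta_new = theta * scale
            _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                      variant, phi, beta, theta_new, ll_i_new, ll_t_new)
            if math.log(np.random.random() + 1e-300) < ll_i_new.sum() - ll_i.sum() + d:
                sig_t = cand
                for t in range(T):
                    theta[t] = theta_new[t]
                    ll_t[t] = ll_t_new[t]
                for i in range(n):
                    ll_i[i] = ll_i_new[i]
                acc = 1.0
        if adapting:
            ls_rt += (acc - 0.44) / (1.0 + sweep) ** 0.6

        # 6. individual effects beta_i: parallel single-site MH (the cell
        # likelihood factorizes over females given the latent states)
        if n > 0:
            step_b = math.exp(ls_beta)
            beta_new = beta + step_b * np.random.normal(0.0, 1.0, n)
            _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                      variant, phi, beta_new, theta, ll_i_new, ll_t_new)
            n_acc = 0
            for i in range(n):
                dpost = (
                    ll_i_new[i] - ll_i[i]
                    + (beta[i] ** 2 - beta_new[i] ** 2) / (2.0 * sig_b**2)
                )
                if math.log(np.random.random() + 1e-300) < dpost:
                    beta[i] = beta_new[i]
                    n_acc += 1
            if adapting:
                ls_beta += (n_acc / n - 0.44) / (1.0 + sweep) ** 0.6
            _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                      variant, phi, beta, theta, ll_i, ll_t)

        # 7. year effects theta_t: parallel single-site MH (cells factorize
        # over target occasions)
        step_t = math.exp(ls_theta)
        theta_new = theta + step_t * np.random.normal(0.0, 1.0, T)
        _cells_ll(b_lat, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                  variant, phi, beta, theta_new, ll_i_new, ll_t_new)
        n_acc = 0
        for t in range(T):
            dpost = (
                ll_t_new[t] - ll_t[t]
                + (theta[t] ** 2 - theta_new[t] ** 2) / (2.0 * sig_t**2)
            )
            if math.log(np.random.random() + 1e-300) < dpost:
                theta[t] = theta_new[t]
                n_acc += 1
        if adapting:
            ls_theta += (n_acc / T - 0.44) / (1.0 + sweep) ** 0.6

        # 8. sigma_beta | beta: exact conditional draw. With a Uniform prior
        # on the sd, x = 1/sigma^2 | effects ~ Gamma((n-1)/2, rate S/2)
        # truncated to the prior bounds (sampled by rejection; the fallback
        # random-walk keeps the chain valid if the region is extreme).
        if n > 0:
            ssq = 0.0
            for i in range(n):
                ssq += beta[i] ** 2
            sig_b = _draw_sigma(sig_b, ssq, n, sb_lo, sb_hi, math.exp(ls_sb))
        else:
            sig_b = sb_lo + (sb_hi - sb_lo) * np.random.random()

        # 9. sigma_theta | theta
        ssq = 0.0
        for t in range(T):
            ssq += theta[t] ** 2
        sig_t = _draw_sigma(sig_t, ssq, T, st_lo, st_hi, math.exp(ls_st))

        # --- store ---
        if not adapting and (sweep - n_burn + 1) % thin == 0 and kept < n_keep:
            for j in range(n_phi):
                phi_out[kept, j] = phi[j]
            for i in range(n):
                beta_out[kept, i] = beta[i]
            for t in range(T):
                theta_out[kept, t] = theta[t]
            sb_out[kept] = sig_b
            st_out[kept] = sig_t
            p_out[kept] = p
            if n > 0:
                _forward_logc(y, recruit, z_age, z_age_sq, z_lw, z_lw_sq, cohort,
                              variant, phi, beta, theta, p, logc)
                for i in range(n):
                    s = 0.0
                    for t in range(T):
                        s += logc[i, t]
                    ll_out[kept, i] = s
            kept += 1

    return phi_out, beta_out, theta_out, sb_out, st_out, p_out, ll_out


# ---------------------------------------------------------------------------
# fitting front end
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    """MCMC protocol. Defaults mirror the analysis protocol (3 chains,
    10,000 burn-in, 100,000 iterations keeping every 100th, i.e. 3,000
    retained draws); tests use explicit scaled-down profiles."""

    n_chains: int = 3
    n_burn: int = 10_000
    n_iter: int = 100_000
    thin: int = 100
    seed: int = 0

    @property
    def n_keep_per_chain(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PriorConfig:
    """Priors: diffuse normals N(0, lambda_sd^2) on all logit-scale fixed
    effects (lambda_sd = sqrt(1000) by default), Uniform(0, 10) on the
    random-effect sds, Uniform(0, 1) on detection."""

    lambda_sd: float = math.sqrt(1000.0)
    sigma_beta_bounds: tuple[float, float] = (0.0, 10.0)
    sigma_theta_bounds: tuple[float, float] = (0.0, 10.0)
    detection_bounds: tuple[float, float] = (0.0, 1.0)


@dataclass
class PosteriorSamples:
    """Posterior draws, indexed chain x draw (vectors: chain x draw x k)."""

    draws: dict[str, np.ndarray]
    variant: str
    n_chains: int
    n_burn: int
    thin: int
    female_ids: list[str] | None = None
    years: np.ndarray | None = None
    max_rhat: float | None = None
    converged: bool | None = None

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.draws["mu"].shape[1]

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]


_SCALAR_BASE = ["mu", "lambda1", "lambda2", "lambda3_F", "lambda3_B"]


def _phi_names(variant: str, n_cohorts: int) -> list[str]:
    names = list(_SCALAR_BASE)
    if variant in ("linear", "quadratic", "parity", "cohort"):
        names.append("lambda5")
    if variant in ("quadratic", "parity"):
        names.append("lambda6")
    if variant == "cohort":
        names += [f"lambda_cohort_{k}" for k in range(1, n_cohorts)]
    return names


def fit_multistate(
    design: MultistateDesign,
    variant: str = "linear",
    config: McmcConfig | None = None,
    priors: PriorConfig | None = None,
) -> PosteriorSamples:
    """Sample the posterior of the multistate transition model.

    The target density is the exact marginal likelihood (forward algorithm,
    equivalently realized by latent-state augmentation) summed over females,
    plus the log-priors of :class:`PriorConfig`. Flags (but does not fail on)
    non-convergence when any split R-hat of a scalar parameter exceeds 1.05.
    """
    code = _check_variant(variant)
    if design.n_females == 0 and design.y.shape[1] == 0:
        raise ValueError("zero-length data")
    config = config or McmcConfig()
    priors = priors or PriorConfig()
    n_phi = _n_phi(code, design.n_cohorts)
    n_keep = config.n_keep_per_chain
    if n_keep < 1:
        raise ValueError("n_iter // thin must be >= 1")

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_chains)]

    per_chain = []
    for c, seed in enumerate(chain_seeds):
        out = _run_chain(
            seed,
            design.y, design.recruit, design.z_age, design.z_age_sq,
            design.z_lw, design.z_lw_sq, design.cohort_index,
            code, n_phi,
            priors.lambda_sd,
            priors.sigma_beta_bounds[0], priors.sigma_beta_bounds[1],
            priors.sigma_theta_bounds[0], priors.sigma_theta_bounds[1],
            priors.detection_bounds[0], priors.detection_bounds[1],
            config.n_burn, n_keep, config.thin,
        )
        per_chain.append(out)
        logger.debug("chain %d/%d finished", c + 1, config.n_chains)

    names = _phi_names(variant, design.n_cohorts)
    draws: dict[str, np.ndarray] = {}
    phi_all = np.stack([pc[0] for pc in per_chain])  # (chains, keep, n_phi)
    for j, name in enumerate(names):
        draws[name] = phi_all[:, :, j]
    draws["lambda3_N"] = -(draws["lambda3_F"] + draws["lambda3_B"])
    draws["beta"] = np.stack([pc[1] for pc in per_chain])
    draws["theta"] = np.stack([pc[2] for pc in per_chain])
    draws["sigma_beta"] = np.stack([pc[3] for pc in per_chain])
    draws["sigma_theta"] = np.stack([pc[4] for pc in per_chain])
    draws["detection_p"] = np.stack([pc[5] for pc in per_chain])
    draws["loglik_female"] = np.stack([pc[6] for pc in per_chain])

    samples = PosteriorSamples(
        draws=draws,
        variant=variant,
        n_chains=config.n_chains,
        n_burn=config.n_burn,
        thin=config.thin,
        female_ids=design.female_ids,
        years=design.years,
    )
    if config.n_chains >= 2 and n_keep >= 10:
        from .evaluate import rhat  # local import to avoid a cycle

        rhats = [
            rhat(draws[name])
            for name in names + ["sigma_beta", "sigma_theta", "detection_p"]
        ]
        samples.max_rhat = float(np.max(rhats))
        samples.converged = bool(samples.max_rhat <= 1.05)
        if not samples.converged:
            logger.warning(
                "possible non-convergence: max split R-hat = %.3f", samples.max_rhat
            )
    return samples


def params_from_draw(samples: PosteriorSamples, chain: int, draw: int) -> TransitionParams:
    """Materialize one posterior draw as a TransitionParams object."""
    d = samples.draws
    l3F = float(d["lambda3_F"][chain, draw])
    l3B = float(d["lambda3_B"][chain, draw])
    lam_coh = None
    coh_names = sorted(k for k in d if k.startswith("lambda_cohort_"))
    if coh_names:
        lam_coh = np.array([d[k][chain, draw] for k in coh_names])
    return TransitionParams(
        mu=float(d["mu"][chain, draw]),
        lambda1=float(d["lambda1"][chain, draw]),
        lambda2=float(d["lambda2"][chain, draw]),
        lambda3=np.array([l3F, l3B, -l3F - l3B]),
        lambda5=float(d["lambda5"][chain, draw]) if "lambda5" in d else 0.0,
        lambda6=float(d["lambda6"][chain, draw]) if "lambda6" in d else 0.0,
        lambda_cohort=lam_coh,
        beta=d["beta"][chain, draw].copy(),
        theta=d["theta"][chain, draw].copy(),
        sigma_beta=float(d["sigma_beta"][chain, draw]),
        sigma_theta=float(d["sigma_theta"][chain, draw]),
        detection_p=float(d["detection_p"][chain, draw]),
    )


def transition_draws(
    samples: PosteriorSamples,
    *,
    std_age: float = 0.0,
    std_age_sq: float = 0.0,
    std_lw: float = 0.0,
    std_lw_sq: float = 0.0,
    parity_group: int = 1,
    cohort_index: int = 0,
) -> dict[str, np.ndarray]:
    """Draw-wise transition probabilities psi^{FB}, psi^{BB}, psi^{NB} at the
    stated covariates (random effects 0)."""
    d = samples.draws
    base = (
        d["mu"]
        + d["lambda1"] * std_age
        + d["lambda2"] * std_age_sq
    )
    if "lambda5" in d:
        base = base + d["lambda5"] * std_lw
    if samples.variant == "quadratic" and "lambda6" in d:
        base = base + d["lambda6"] * std_lw_sq
    if samples.variant == "parity" and "lambda6" in d and parity_group == 1:
        base = base + d["lambda6"] * std_lw
    if samples.variant == "cohort" and cohort_index > 0:
        base = base + d[f"lambda_cohort_{cohort_index}"]
    out = {}
    for k, name in zip(("F", "B", "N"), ("psi_FB", "psi_BB", "psi_NB")):
        lam3 = d[f"lambda3_{k}"]
        lp = base + lam3
        out[name] = (1.0 / (1.0 + np.exp(-lp))).reshape(-1)
    return out


def transition_summary(samples: PosteriorSamples, **at_covariates) -> "pd.DataFrame":
    """Posterior mean, sd and 2.5/50/97.5% quantiles of the transition rates
    psi^{FB}, psi^{BB}, psi^{NB} evaluated at the stated covariates
    (defaults: mean age, mean L_w, random effects 0)."""
    import pandas as pd

    psis = transition_draws(samples, **at_covariates)
    rows = []
    for name, arr in psis.items():
        rows.append(
            {
                "transition": name,
                "mean": arr.mean(),
                "sd": arr.std(ddof=1) if arr.size > 1 else 0.0,
                "q2.5": np.quantile(arr, 0.025),
                "q50": np.quantile(arr, 0.5),
                "q97.5": np.quantile(arr, 0.975),
            }
        )
    return pd.DataFrame(rows).set_index("transition")
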
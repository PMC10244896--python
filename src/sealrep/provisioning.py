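"""Linear mixed models for pup weaning mass (maternal provisioning).

Gray seal mothers fast through lactation, so a pup's mass at weaning measures
the energy its mother transferred. Weaning mass of pup j born to female i in
year t is modeled as

    mass_{j,t} = intercept + pi1*age_z + pi2*age2_z + pi3[parity]
                 + pi4*I(sex = female) + (weaning-length terms)
                 + alpha_i + eta_t + eps_{j,t}

with crossed random intercepts for female (alpha ~ N(0, sigma_alpha^2)) and
year (eta ~ N(0, sigma_eta^2)) and residual eps ~ N(0, sigma_resid^2). Age,
age^2, L_w and L_w^2 enter as separately z-scored columns; parity is
discretized 1 / 2 / 3+ (baseline 1); the sex indicator is 1 for female pups.

Model variants mirror the provisioning model menu: null, a linear L_w term,
a quadratic L_w term, an L_w-by-parity interaction (which replaces the
parity main effects), and per-cohort offsets.

Fitting maximizes the likelihood profiled over the fixed effects and the
residual variance: with variance ratios g = (sigma_alpha^2, sigma_eta^2) /
sigma_resid^2, the marginal covariance is sigma_resid^2 * W(g) with
W = I + Z G Z', and the two log-ratios are optimized by bounded
quasi-Newton from multiple starts. W-solves use the Woodbury identity, so
each objective evaluation costs one Cholesky of a q x q matrix (q = number
of females + years). ML is the default so that likelihood-ratio tests on
fixed effects are valid; REML is available by flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import Standardizer, derive_parity, fit_standardizer

logger = logging.getLogger("sealrep")

__all__ = [
    "MASS_VARIANTS",
    "MassParams",
    "LmmFit",
    "build_mass_design",
    "fit_mass_model",
    "likelihood_ratio_test",
    "variance_partition",
    "predict_mass_spread",
]

MASS_VARIANTS = ("null", "linear", "quadratic", "parity", "cohort")


@dataclass
class MassParams:
    """Generating/estimated parameters of the provisioning model.

    ``pi3_2``/``pi3_3`` are the parity-2 and parity-3+ effects relative to a
    first birth; ``pi4`` is the female-pup effect; ``pi5``..``pi7`` are the
    weaning-length terms (variant dependent). The sigmas are standard
    deviations in kg.
    """

    intercept: float = 0.0
    pi1: float = 0.0
    pi2: float = 0.0
    pi3_2: float = 0.0
    pi3_3: float = 0.0
    pi4: float = 0.0
    pi5: float = 0.0
    pi6: float = 0.0
    pi7: float = 0.0
    pi_cohort: np.ndarray | None = None
    sigma_alpha: float = 0.0
    sigma_eta: float = 0.0
    sigma_resid: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma_alpha, self.sigma_eta, self.sigma_resid) < 0:
            raise ValueError("sds must be >= 0")


@dataclass
class MassDesign:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    female_codes: np.ndarray
    year_codes: np.ndarray
    n_females: int
    n_years: int
    standardizers: dict[str, Standardizer]


@dataclass
class LmmFit:
    """A fitted provisioning model."""

    variant: str
    fixed_names: list[str]
    fixed: np.ndarray
    se: np.ndarray
    cov_fixed: np.ndarray
    sigma_alpha: float
    sigma_eta: float
    sigma_resid: float
    loglik: float
    n_obs: int
    k_params: int
    converged: bool
    reml: bool
    standardizers: dict[str, Standardizer]

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    @property
    def estimates(self) -> MassParams:
        get = dict(zip(self.fixed_names, self.fixed))
        coh = sorted(k for k in get if k.startswith("cohort_"))
        return MassParams(
            intercept=get.get("intercept", 0.0),
            pi1=get.get("z_age", 0.0),
            pi2=get.get("z_age_sq", 0.0),
            pi3_2=get.get("parity_2", 0.0),
            pi3_3=get.get("parity_3", 0.0),
            pi4=get.get("sex_female", 0.0),
            pi5=get.get("z_lw", 0.0),
            pi6=get.get("z_lw_sq", get.get("z_lw_x_parity_2", 0.0)),
            pi7=get.get("z_lw_x_parity_3", 0.0),
            pi_cohort=np.array([get[k] for k in coh]) if coh else None,
            sigma_alpha=self.sigma_alpha,
            sigma_eta=self.sigma_eta,
            sigma_resid=self.sigma_resid,
        )

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.fixed, "se": self.se}, index=self.fixed_names
        )


def build_mass_design(
    pup_table: pd.DataFrame,
    female_table: pd.DataFrame,
    variant: str = "null",
    *,
    standardizers: dict[str, Standardizer] | None = None,
) -> MassDesign:
    """Assemble response and design matrix for a model variant.

    Parity is derived from the observed birth records (cumulative count,
    discretized 1/2/3+). Standardization constants default to the analysis
    sample; pass ``standardizers`` to use externally fixed constants.
    """
    if variant not in MASS_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {MASS_VARIANTS}")
    df = pup_table.merge(
        female_table[["female_id", "cohort", "weaning_length_cm"]],
        on="female_id",
        how="left",
        validate="many_to_one",
    )
    if df["weaning_length_cm"].isna().any():
        missing = df.loc[df.weaning_length_cm.isna(), "female_id"].unique()
        raise ValueError(f"pup records without female covariates: {missing[:5]}")
    df = df.reset_index(drop=True)
    if df["female_id"].nunique() < 2 or df["year"].nunique() < 2:
        raise ValueError("need at least 2 females and 2 years")
    df["parity_group"] = derive_parity(df).to_numpy()

    age = df["maternal_age_yr"].to_numpy(dtype=float)
    lw = df["weaning_length_cm"].to_numpy(dtype=float)
    if standardizers is None:
        # L_w constants come from the female sample (one value per female),
        # not the pup rows, so prolific mothers don't dominate the scale.
        per_female = df.drop_duplicates("female_id")["weaning_length_cm"].to_numpy(float)
        standardizers = {
            "age": fit_standardizer(age),
            "age_sq": fit_standardizer(age**2),
            "lw": fit_standardizer(per_female),
            "lw_sq": fit_standardizer(per_female**2),
        }
    z_age = standardizers["age"].transform(age)
    z_age_sq = standardizers["age_sq"].transform(age**2)
    z_lw = standardizers["lw"].transform(lw)
    z_lw_sq = standardizers["lw_sq"].transform(lw**2)

    par2 = (df["parity_group"] == 2).to_numpy(float)
    par3 = (df["parity_group"] == 3).to_numpy(float)
    sexf = (df["pup_sex"] == "female").to_numpy(float)

    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(df)))]
    cols += [("z_age", z_age), ("z_age_sq", z_age_sq)]
    if variant != "parity":
        cols += [("parity_2", par2), ("parity_3", par3)]
    cols += [("sex_female", sexf)]
    if variant in ("linear", "quadratic", "parity", "cohort"):
        cols += [("z_lw", z_lw)]
    if variant == "quadratic":
        cols += [("z_lw_sq", z_lw_sq)]
    if variant == "parity":
        cols += [
            ("z_lw_x_parity_2", z_lw * par2),
            ("z_lw_x_parity_3", z_lw * par3),
        ]
    if variant == "cohort":
        uniq = np.sort(df["cohort"].unique())
        for c in uniq[1:]:
            cols += [(f"cohort_{c}", (df["cohort"] == c).to_numpy(float))]

    X = np.column_stack([v for _, v in cols])
    names = [k for k, _ in cols]
    # singular-design guard: a missing level must be reported, not dropped
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design for variant {variant!r} "
            f"(rank {rank} < {X.shape[1]}); check for absent factor levels"
        )

    f_codes, f_uniq = pd.factorize(df["female_id"], sort=True)
    y_codes, y_uniq = pd.factorize(df["year"], sort=True)
    return MassDesign(
        y=df["weaning_mass_kg"].to_numpy(float),
        X=X,
        fixed_names=names,
        female_codes=f_codes.astype(np.int64),
        year_codes=y_codes.astype(np.int64),
        n_females=len(f_uniq),
        n_years=len(y_uniq),
        standardizers=standardizers,
    )


# ---------------------------------------------------------------------------
# profiled ML / REML
# ---------------------------------------------------------------------------


class _ProfiledLmm:
    """Deviance of the crossed-intercepts LMM profiled over fixed effects and
    residual variance, as a function of the two log variance ratios."""

    def __init__(self, y, X, f_codes, y_codes, qf, qy, reml=False):
        self.n, self.p = X.shape
        self.qf, self.qy = qf, qy
        self.q = qf + qy
        self.reml = reml
        n, q = self.n, self.q
        Z_idx_f = f_codes
        Z_idx_y = qf + y_codes
        # sufficient statistics: Z'Z, Z'X, Z'y, X'X, X'y, y'y
        A = np.zeros((q, q))
        np.add.at(A, (Z_idx_f, Z_idx_f), 1.0)
        np.add.at(A, (Z_idx_y, Z_idx_y), 1.0)
        np.add.at(A, (Z_idx_f, Z_idx_y), 1.0)
        np.add.at(A, (Z_idx_y, Z_idx_f), 1.0)
        ZtX = np.zeros((q, self.p))
        np.add.at(ZtX, Z_idx_f, X)
        np.add.at(ZtX, Z_idx_y, X)
        Zty = np.zeros(q)
        np.add.at(Zty, Z_idx_f, y)
        np.add.at(Zty, Z_idx_y, y)
        self.A, self.ZtX, self.Zty = A, ZtX, Zty
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _whitened(self, log_g):
        gf, gy = np.exp(log_g)
        s = np.sqrt(np.concatenate([np.full(self.qf, gf), np.full(self.qy, gy)]))
        M = self.A * np.outer(s, s)
        M[np.diag_indices_from(M)] += 1.0
        cf = linalg.cho_factor(M, lower=True)
        logdet_W = 2.0 * np.log(np.diag(cf[0])).sum()
        SU = s[:, None] * self.ZtX  # S Z'X
        Sv = s * self.Zty
        MinvSU = linalg.cho_solve(cf, SU)
        MinvSv = linalg.cho_solve(cf, Sv)
        XtWX = self.XtX - SU.T @ MinvSU
        XtWy = self.Xty - SU.T @ MinvSv
        ytWy = self.yty - Sv @ MinvSv
        return XtWX, XtWy, ytWy, logdet_W

    def profile(self, log_g):
        """Return (-2 loglik, beta, cov_unscaled, sigma2_resid, logdet terms)."""
        XtWX, XtWy, ytWy, logdet_W = self._whitened(log_g)
        cfx = linalg.cho_factor(XtWX)
        beta = linalg.cho_solve(cfx, XtWy)
        rss = max(ytWy - beta @ XtWy, 1e-300)
        if self.reml:
            dof = self.n - self.p
            sigma2 = rss / dof
            logdet_X = 2.0 * np.log(np.diag(cfx[0])).sum()
            dev = dof * math.log(2.0 * math.pi * sigma2) + logdet_W + logdet_X + dof
        else:
            sigma2 = rss / self.n
            dev = self.n * math.log(2.0 * math.pi * sigma2) + logdet_W + self.n
        return dev, beta, cfx, sigma2

    def deviance(self, log_g):
        return self.profile(log_g)[0]


_STARTS = (np.array([-2.0, -2.0]), np.array([0.0, 0.0]), np.array([1.5, 0.0]))
_BOUNDS = [(-14.0, 8.0), (-14.0, 8.0)]


def fit_mass_model(
    pup_table: pd.DataFrame,
    female_table: pd.DataFrame,
    variant: str = "null",
    *,
    reml: bool = False,
    standardizers: dict[str, Standardizer] | None = None,
) -> LmmFit:
    """Fit one provisioning-model variant by (RE)ML.

    Deterministic given the data: bounded L-BFGS-B on the profiled deviance
    in the two log variance ratios, from three fixed starting points.
    """
    design = build_mass_design(pup_table, female_table, variant, standardizers=standardizers)
    if design.n_females < 2 or design.n_years < 2:
        raise ValueError("need at least 2 females and 2 years")
    prof = _ProfiledLmm(
        design.y, design.X, design.female_codes, design.year_codes,
        design.n_females, design.n_years, reml=reml,
    )
    best = None
    ok = False
    for x0 in _STARTS:
        res = optimize.minimize(
            prof.deviance, x0, method="L-BFGS-B", bounds=_BOUNDS,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        ok = ok or res.success
    dev, beta, cfx, sigma2 = prof.profile(best.x)
    cov_fixed = sigma2 * linalg.cho_solve(cfx, np.eye(len(beta)))
    gf, gy = np.exp(best.x)
    k = design.X.shape[1] + 3  # fixed effects + three variance components
    fit = LmmFit(
        variant=variant,
        fixed_names=design.fixed_names,
        fixed=beta,
        se=np.sqrt(np.diag(cov_fixed)),
        cov_fixed=cov_fixed,
        sigma_alpha=math.sqrt(gf * sigma2),
        sigma_eta=math.sqrt(gy * sigma2),
        sigma_resid=math.sqrt(sigma2),
        loglik=-0.5 * dev,
        n_obs=design.y.size,
        k_params=k,
        converged=ok,
        reml=reml,
        standardizers=design.standardizers,
    )
    if not ok:
        logger.warning("variant %s: optimizer did not report convergence", variant)
    return fit


def likelihood_ratio_test(fit_nested: LmmFit, fit_full: LmmFit) -> tuple[float, int, float]:
    """LRT of a nested against a full variant fitted to the same data.

    Returns (statistic, df, p). The statistic is 2*(loglik_full -
    loglik_nested), clipped at 0 for identical models; p is the chi-square
    upper tail. Raises for non-nested fixed-effect sets or differing n.
    """
    if fit_nested.n_obs != fit_full.n_obs:
        raise ValueError("fits use different numbers of observations")
    if fit_nested.reml or fit_full.reml:
        raise ValueError("LRT on fixed effects requires ML fits")
    nested_set = set(fit_nested.fixed_names)
    full_set = set(fit_full.fixed_names)
    if not nested_set <= full_set:
        raise ValueError(
            f"models are not nested: {sorted(nested_set - full_set)} "
            "absent from the full model"
        )
    df = len(full_set) - len(nested_set)
    stat = max(2.0 * (fit_full.loglik - fit_nested.loglik), 0.0)
    if df == 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def variance_partition(fit: LmmFit) -> dict[str, float]:
    """Share of total variance (individual + year + residual) per component."""
    comps = {
        "individual": fit.sigma_alpha**2,
        "year": fit.sigma_eta**2,
        "residual": fit.sigma_resid**2,
    }
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("all variance components are zero")
    return {k: v / total for k, v in comps.items()}


def predict_mass_spread(
    fit: LmmFit,
    lw_low_cm: float = 90.0,
    lw_high_cm: float = 132.0,
    *,
    at_parity: int = 1,
    z_level: float = 1.96,
) -> dict[str, float]:
    """Expected weaning-mass difference (kg) between two maternal weaning
    lengths, all other covariates held fixed, with a normal-approximation
    interval from the fixed-effect covariance.

    Only L_w-dependent design columns differ between the two predictions, so
    for the linear variant the spread is exactly pi5 * (z(high) - z(low)).
    """
    lw_names = [n for n in fit.fixed_names if n.startswith("z_lw")]
    if not lw_names:
        raise ValueError(f"variant {fit.variant!r} has no weaning-length term")
    std_lw = fit.standardizers["lw"]
    lo_obs = std_lw.inverse(-3.0)
    hi_obs = std_lw.inverse(3.0)
    if not (lo_obs <= lw_low_cm <= hi_obs and lo_obs <= lw_high_cm <= hi_obs):
        logger.warning(
            "weaning length outside ~observed range [%.0f, %.0f] cm", lo_obs, hi_obs
        )

    def lw_columns(lw_cm: float) -> np.ndarray:
        z = float(std_lw.transform(lw_cm))
        vals = {}
        vals["z_lw"] = z
        if "z_lw_sq" in fit.fixed_names:
            vals["z_lw_sq"] = float(fit.standardizers["lw_sq"].transform(lw_cm**2))
        if "z_lw_x_parity_2" in fit.fixed_names:
            vals["z_lw_x_parity_2"] = z * (at_parity == 2)
            vals["z_lw_x_parity_3"] = z * (at_parity == 3)
        return np.array([vals[n] for n in lw_names])

    contrast = np.zeros(len(fit.fixed_names))
    idx = [fit.fixed_names.index(n) for n in lw_names]
    contrast[idx] = lw_columns(lw_high_cm) - lw_columns(lw_low_cm)
    spread = float(contrast @ fit.fixed)
    se = float(np.sqrt(contrast @ fit.cov_fixed @ contrast))
    return {
        "spread_kg": spread,
        "se": se,
        "ci_low": spread - z_level * se,
        "ci_high": spread + z_level * se,
    }
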
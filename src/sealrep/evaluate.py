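"""Posterior diagnostics, model comparison and the run report.

WAIC here uses the female's whole post-recruitment history as the pointwise
observation unit by default: within-female occasions are dependent through
the individual random effect, so per-occasion terms would overstate the
effective sample size. A per-occasion option is provided for sensitivity.

The cost-of-reproduction contrast is the draw-wise difference
psi^{BB} - psi^{NB}: a negative value means having bred last year lowers
this year's breeding probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .multistate import (
    MultistateDesign,
    PosteriorSamples,
    _forward_logc,
    _VARIANT_CODE,
    _phi_names,
    transition_draws,
    transition_summary,
)

logger = logging.getLogger("sealrep")

__all__ = [
    "WaicResult",
    "ContrastResult",
    "waic",
    "rhat",
    "rhat_table",
    "cost_contrast",
    "build_report",
    "Report",
]


@dataclass
class WaicResult:
    """Widely Applicable Information Criterion; smaller is better."""

    lppd: float
    p_waic: float
    waic: float
    pointwise: pd.DataFrame  # per-observation lppd and p_waic contributions
    pointwise_unit: str

    def __post_init__(self) -> None:
        assert abs(self.waic - (-2.0 * (self.lppd - self.p_waic))) < 1e-8


def _pointwise_loglik(samples: PosteriorSamples, design: MultistateDesign,
                      per_occasion: bool) -> np.ndarray:
    """(draws, obs) log-likelihood matrix recomputed from the stored draws
    via the forward algorithm."""
    code = _VARIANT_CODE[samples.variant]
    names = _phi_names(samples.variant, design.n_cohorts)
    d = samples.draws
    n_chains, n_keep = d["mu"].shape
    n, T = design.y.shape
    logc = np.zeros((n, T))
    out = []
    for c in range(n_chains):
        for k in range(n_keep):
            phi = np.array([d[name][c, k] for name in names])
            _forward_logc(
                design.y, design.recruit, design.z_age, design.z_age_sq,
                design.z_lw, design.z_lw_sq, design.cohort_index,
                code, phi, d["beta"][c, k], d["theta"][c, k],
                float(d["detection_p"][c, k]), logc,
            )
            if per_occasion:
                mask = np.arange(T)[None, :] > design.recruit[:, None]
                out.append(logc[mask].copy())
            else:
                out.append(logc.sum(axis=1))
    return np.asarray(out)


def waic(
    samples: PosteriorSamples,
    design: MultistateDesign | None = None,
    *,
    pointwise: str = "female",
) -> WaicResult:
    """Compute WAIC from posterior draws.

    lppd_i = log mean_s exp(loglik_{s,i}); p_waic_i = var_s loglik_{s,i}.
    With ``pointwise="female"`` (default) the stored per-female marginal
    log-likelihoods are used; ``pointwise="occasion"`` recomputes one term
    per post-recruitment occasion (requires ``design``).
    """
    if pointwise not in ("female", "occasion"):
        raise ValueError("pointwise must be 'female' or 'occasion'")
    if pointwise == "occasion":
        if design is None:
            raise ValueError("per-occasion WAIC needs the design")
        ll = _pointwise_loglik(samples, design, per_occasion=True)
    elif "loglik_female" in samples.draws:
        ll = samples.stacked("loglik_female")
    else:
        if design is None:
            raise ValueError("samples carry no stored log-likelihoods; pass design")
        ll = _pointwise_loglik(samples, design, per_occasion=False)
    S = ll.shape[0]
    if S < 2:
        raise ValueError("need at least 2 posterior draws for WAIC")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    lppd, p_waic = float(lppd_i.sum()), float(p_i.sum())
    return WaicResult(
        lppd=lppd,
        p_waic=p_waic,
        waic=-2.0 * (lppd - p_waic),
        pointwise=pd.DataFrame({"lppd": lppd_i, "p_waic": p_i}),
        pointwise_unit=pointwise,
    )


def rhat(chains: np.ndarray | dict, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is a (n_chains, n_draws) array (or a PosteriorSamples plus a
    parameter name). Each chain is split in half; R-hat compares between- to
    within-half variance and is >= 1 up to numerical tolerance.
    """
    if isinstance(chains, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorSamples")
        chains = chains.draws[parameter]
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    if x.shape[1] < 10:
        raise ValueError("need >= 10 draws per chain")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    B = n * chain_means.var(ddof=1)
    W = splits.var(axis=1, ddof=1).mean()
    if W <= 0.0:
        return 1.0 if B <= 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat_table(samples: PosteriorSamples) -> pd.Series:
    """Split R-hat for every scalar parameter."""
    return pd.Series(
        {name: rhat(samples.draws[name]) for name in samples.scalar_names()
         if name != "loglik_female"},
        name="rhat",
    )


@dataclass
class ContrastResult:
    """Posterior of the reproduction-cost contrast psi^{BB} - psi^{NB}."""

    draws: np.ndarray
    mean: float
    cri_low: float
    cri_high: float
    prob_negative: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.prob_negative <= 1.0
        if not (self.cri_low - 1e-12 <= self.mean <= self.cri_high + 1e-12):
            # can only happen for a heavily skewed (e.g. unconverged)
            # posterior: the mean is not guaranteed inside an equal-tailed
            # interval, so flag rather than fail
            logger.warning(
                "contrast mean %.4f outside the 95%% CRI (%.4f, %.4f)",
                self.mean, self.cri_low, self.cri_high,
            )


def cost_contrast(samples: PosteriorSamples, **at_covariates) -> ContrastResult:
    """Draw-wise psi^{BB} - psi^{NB} at the stated covariates (defaults:
    standardized age 0, standardized L_w 0, random effects 0). A negative
    contrast is a cost of reproduction."""
    psis = transition_draws(samples, **at_covariates)
    diff = psis["psi_BB"] - psis["psi_NB"]
    return ContrastResult(
        draws=diff,
        mean=float(diff.mean()),
        cri_low=float(np.quantile(diff, 0.025)),
        cri_high=float(np.quantile(diff, 0.975)),
        prob_negative=float((diff < 0).mean()),
    )


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------


@dataclass
class Report:
    mass_comparison: pd.DataFrame
    mass_coefficients: pd.DataFrame
    multistate_comparison: pd.DataFrame
    multistate_coefficients: pd.DataFrame
    transition_rates: pd.DataFrame
    contrast: ContrastResult | None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "mass_comparison": self.mass_comparison,
            "mass_coefficients": self.mass_coefficients,
            "multistate_comparison": self.multistate_comparison,
            "multistate_coefficients": self.multistate_coefficients,
            "transition_rates": self.transition_rates,
        }


def _mass_comparison(mass_fits: list) -> pd.DataFrame:
    from .provisioning import likelihood_ratio_test

    null = next((f for f in mass_fits if f.variant == "null"), None)
    rows = []
    for f in mass_fits:
        row = {
            "variant": f.variant,
            "k": f.k_params,
            "loglik": f.loglik,
            "AIC": f.aic,
        }
        if null is not None and f is not null:
            try:
                stat, df, p = likelihood_ratio_test(null, f)
                row["LRT_p"] = p
            except ValueError:
                row["LRT_p"] = float("nan")  # non-nested (e.g. parity variant)
        else:
            row["LRT_p"] = float("nan")
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variant")
    out["dAIC"] = out["AIC"] - out["AIC"].min()
    return out


def _posterior_coef_table(samples: PosteriorSamples) -> pd.DataFrame:
    rows = []
    for name in samples.scalar_names():
        if name == "loglik_female":
            continue
        flat = samples.stacked(name)
        rows.append(
            {
                "parameter": name,
                "rhat": rhat(samples.draws[name]),
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.quantile(flat, 0.025),
                "q50": np.quantile(flat, 0.5),
                "q97.5": np.quantile(flat, 0.975),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def build_report(
    mass_fits: list,
    multistate_results: list[tuple[PosteriorSamples, WaicResult]],
    outdir: str | Path | None = None,
) -> Report:
    """Assemble the result tables (model menus with AIC/WAIC and deltas,
    coefficient tables with posterior quantiles and R-hat, transition rates,
    cost contrast) and optionally write CSVs plus summary figures."""
    if not mass_fits or not multistate_results:
        raise ValueError("need at least one fitted model per family")
    mass_cmp = _mass_comparison(mass_fits)
    best_mass = mass_fits[int(np.argmin([f.aic for f in mass_fits]))]
    mass_coefs = best_mass.coef_table()
    mass_coefs["variant"] = best_mass.variant

    ms_rows = []
    for samples, w in multistate_results:
        ms_rows.append(
            {
                "variant": samples.variant,
                "WAIC": w.waic,
                "p_waic": w.p_waic,
                "max_rhat": samples.max_rhat,
            }
        )
    ms_cmp = pd.DataFrame(ms_rows).set_index("variant")
    ms_cmp["dWAIC"] = ms_cmp["WAIC"] - ms_cmp["WAIC"].min()
    best_idx = int(np.argmin([w.waic for _, w in multistate_results]))
    best_samples = multistate_results[best_idx][0]
    ms_coefs = _posterior_coef_table(best_samples)
    rates = transition_summary(best_samples)
    contrast = cost_contrast(best_samples)

    report = Report(
        mass_comparison=mass_cmp,
        mass_coefficients=mass_coefs,
        multistate_comparison=ms_cmp,
        multistate_coefficients=ms_coefs,
        transition_rates=rates,
        contrast=contrast,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in report.tables().items():
            table.to_csv(outdir / f"{name}.csv")
        pd.Series(
            {
                "contrast_mean": contrast.mean,
                "contrast_cri_low": contrast.cri_low,
                "contrast_cri_high": contrast.cri_high,
                "prob_cost": contrast.prob_negative,
            }
        ).to_csv(outdir / "cost_contrast.csv", header=False)
        _write_figures(best_mass, best_samples, contrast, outdir)
    return report


def _write_figures(best_mass, best_samples, contrast, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # provisioning effect of L_w
    if "z_lw" in best_mass.fixed_names:
        std = best_mass.standardizers["lw"]
        lw = np.linspace(90, 132, 50)
        z = std.transform(lw)
        j = best_mass.fixed_names.index("z_lw")
        eff = best_mass.fixed[j] * z
        se = best_mass.se[j] * np.abs(z)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(lw, eff, color="k")
        ax.fill_between(lw, eff - 1.96 * se, eff + 1.96 * se, alpha=0.25)
        ax.set_xlabel("maternal weaning length (cm)")
        ax.set_ylabel("effect on pup weaning mass (kg)")
        fig.tight_layout()
        fig.savefig(outdir / "mass_vs_lw.svg")
        plt.close(fig)

    # breeding probability vs L_w (posterior mean and CRI)
    if "lambda5" in best_samples.draws:
        zs = np.linspace(-3, 3, 31)
        med, lo, hi = [], [], []
        for z in zs:
            psi = transition_draws(best_samples, std_lw=float(z))["psi_BB"]
            med.append(np.median(psi))
            lo.append(np.quantile(psi, 0.025))
            hi.append(np.quantile(psi, 0.975))
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(zs, med, color="k")
        ax.fill_between(zs, lo, hi, alpha=0.25)
        ax.set_xlabel("standardized weaning length")
        ax.set_ylabel(r"breeding probability $\psi^{BB}$")
        fig.tight_layout()
        fig.savefig(outdir / "breeding_vs_lw.svg")
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(contrast.draws, bins=40, density=True, alpha=0.7)
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel(r"$\psi^{BB} - \psi^{NB}$")
    ax.set_ylabel("posterior density")
    fig.tight_layout()
    fig.savefig(outdir / "cost_contrast.svg")
    plt.close(fig)
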
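import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sealrep.data import EncounterHistory
from sealrep.multistate import (
    FemaleCovariates,
    McmcConfig,
    MultistateDesign,
    TransitionParams,
    breeding_probability,
    brute_force_loglik,
    build_design,
    fit_multistate,
    forward_loglik,
    transition_summary,
    _forward_logc,
    _phi_names,
)


def _logit(p):
    return math.log(p / (1 - p))


def _history(bits, start=2000):
    return EncounterHistory("F", np.array(bits), np.arange(start, start + len(bits)))


def _covariates(T, rng=None, flat=False):
    if flat or rng is None:
        return FemaleCovariates(std_age=np.zeros(T), std_age_sq=np.zeros(T))
    return FemaleCovariates(
        std_age=rng.normal(0, 1, T),
        std_age_sq=rng.normal(0, 1, T),
        std_lw=float(rng.normal()),
        std_lw_sq=float(rng.normal()),
        cohort_index=int(rng.integers(0, 5)),
    )


def _random_params(rng, T):
    lam3 = rng.normal(0, 0.7, 2)
    return TransitionParams(
        mu=float(rng.normal()),
        lambda1=float(rng.normal(0, 0.5)),
        lambda2=float(rng.normal(0, 0.5)),
        lambda3=np.array([lam3[0], lam3[1], -lam3.sum()]),
        lambda5=float(rng.normal(0, 0.5)),
        lambda6=float(rng.normal(0, 0.5)),
        lambda_cohort=rng.normal(0, 0.5, 4),
        theta=rng.normal(0, 0.8, T),
        beta=np.array([rng.normal(0, 0.8)]),
        sigma_beta=0.8,
        sigma_theta=0.8,
        detection_p=float(rng.uniform(0.3, 1.0)),
    )


class TestTransitionParams:
    def test_sum_to_zero_enforced(self):
        with pytest.raises(ValueError, match="sum to zero"):
            TransitionParams(lambda3=np.array([0.1, 0.1, 0.1]))

    def test_from_transition_rates_reproduces_rates(self):
        tp = TransitionParams.from_transition_rates(0.779, 0.861, 0.878)
        for prev, psi in zip("FBN", (0.779, 0.861, 0.878)):
            got = breeding_probability(tp, prev, 0.0, 0.0, variant="null")
            assert got == pytest.approx(psi, abs=1e-12)
        assert abs(tp.lambda3.sum()) < 1e-12


class TestBreedingProbability:
    def test_all_zero_parameters_give_half(self):
        tp = TransitionParams()
        for prev in "FBN":
            assert breeding_probability(tp, prev, 0.7, -1.2, variant="null") == 0.5

    def test_intercept_anchor(self):
        tp = TransitionParams(mu=_logit(0.861))
        assert breeding_probability(tp, "B", 0.0, 0.0, variant="null") == pytest.approx(
            0.861
        )

    def test_monotone_in_weaning_length(self):
        tp = TransitionParams(lambda5=0.549)
        probs = [
            breeding_probability(tp, "B", 0.0, z, variant="linear")
            for z in np.linspace(-2, 2, 9)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="state"):
            breeding_probability(TransitionParams(), "X", 0.0, 0.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            breeding_probability(TransitionParams(), "B", 0.0, 0.0, variant="cubic")


class TestForwardLoglik:
    def test_recruitment_only_history_has_zero_loglik(self):
        h = _history([1])
        cov = _covariates(1, flat=True)
        assert forward_loglik(h, cov, TransitionParams(), "null") == 0.0
        assert brute_force_loglik(h, cov, TransitionParams(), "null") == 0.0

    def test_one_missed_occasion_with_perfect_detection(self):
        # after recruitment the only consistent latent path is N, so the
        # marginal probability is 1 - psi_FB
        tp = TransitionParams(mu=_logit(0.779), detection_p=1.0)
        h = _history([1, 0])
        got = forward_loglik(h, _covariates(2, flat=True), tp, "null")
        assert got == pytest.approx(math.log(1 - 0.779), abs=1e-12)

    def test_bruteforce_single_path(self):
        psi_FB, psi_BB = 0.779, 0.861
        tp = TransitionParams.from_transition_rates(psi_FB, psi_BB, 0.9,
                                                    detection_p=1.0)
        # verify the implied rates before using them
        assert breeding_probability(tp, "F", 0, 0, variant="null") == pytest.approx(psi_FB)
        assert breeding_probability(tp, "B", 0, 0, variant="null") == pytest.approx(psi_BB)
        h = _history([1, 1, 0])
        got = brute_force_loglik(h, _covariates(3, flat=True), tp, "null")
        assert got == pytest.approx(math.log(psi_FB * (1 - psi_BB)), abs=1e-12)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_forward_equals_bruteforce(self, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 9))
        r = int(rng.integers(0, T - 1))
        y = np.zeros(T, dtype=int)
        y[r] = 1
        y[r + 1:] = rng.integers(0, 2, T - r - 1)
        variant = ["null", "linear", "quadratic", "parity", "cohort"][seed % 5]
        params = _random_params(rng, T)
        cov = _covariates(T, rng)
        h = _history(y.tolist())
        a = forward_loglik(h, cov, params, variant)
        b = brute_force_loglik(h, cov, params, variant)
        if math.isinf(a):
            assert math.isinf(b)
        else:
            assert a == pytest.approx(b, abs=1e-10)

    def test_numba_kernel_matches_reference(self, small_colony):
        from conftest import filtered_tables

        histories, females, _ = filtered_tables(small_colony)
        design = build_design(histories, females,
                              standardizers=small_colony.standardizers)
        rng = np.random.default_rng(5)
        lam3 = rng.normal(0, 0.5, 2)
        tp = TransitionParams(
            mu=1.2, lambda1=0.3, lambda2=-0.2,
            lambda3=np.array([lam3[0], lam3[1], -lam3.sum()]),
            lambda5=0.5,
            beta=rng.normal(0, 0.5, design.n_females),
            theta=rng.normal(0, 0.5, design.n_occasions),
            sigma_beta=0.5, sigma_theta=0.5, detection_p=0.93,
        )
        phi = np.array([tp.mu, tp.lambda1, tp.lambda2, tp.lambda3[0],
                        tp.lambda3[1], tp.lambda5])
        logc = np.zeros((design.n_females, design.n_occasions))
        _forward_logc(design.y, design.recruit, design.z_age, design.z_age_sq,
                      design.z_lw, design.z_lw_sq, design.cohort_index,
                      1, phi, tp.beta, tp.theta, tp.detection_p, logc)
        for i, h in enumerate(histories):
            ref = forward_loglik(h, design.covariates(i), tp, "linear",
                                 female_index=i)
            assert logc[i].sum() == pytest.approx(ref, abs=1e-10)

    def test_perfect_detection_closed_form(self):
        # with p = 1 the sighting vector reveals the latent states, so the
        # marginal likelihood is the product of the implied transition probs
        rng = np.random.default_rng(8)
        tp = _random_params(rng, 5)
        tp.detection_p = 1.0
        tp.beta = np.zeros(1)
        tp.theta = np.zeros(5)
        cov = _covariates(5, rng)
        for code in range(2**4):
            bits = [(code >> j) & 1 for j in range(4)]
            h = _history([1] + bits)
            expected = 0.0
            prev, births = "F", 1
            for j, b in enumerate(bits):
                psi = breeding_probability(
                    tp, prev, float(cov.std_age[j + 1]), cov.std_lw,
                    std_age_sq=float(cov.std_age_sq[j + 1]),
                    std_lw_sq=cov.std_lw_sq, parity_group=min(births, 3),
                    cohort_index=cov.cohort_index, variant="parity",
                )
                expected += math.log(psi if b else 1 - psi)
                prev = "B" if b else "N"
                births += b
            got = forward_loglik(h, cov, tp, "parity")
            assert got == pytest.approx(expected, abs=1e-12)

    def test_loglik_invariant_to_female_permutation(self, small_colony):
        from conftest import filtered_tables

        histories, females, _ = filtered_tables(small_colony)
        design = build_design(histories, females,
                              standardizers=small_colony.standardizers)
        tp = TransitionParams(mu=1.5, lambda5=0.5, detection_p=0.95)
        total = sum(
            forward_loglik(h, design.covariates(i), tp, "linear")
            for i, h in enumerate(histories)
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(histories))
        total_perm = sum(
            forward_loglik(histories[j], design.covariates(j), tp, "linear")
            for j in perm
        )
        assert total == pytest.approx(total_perm, abs=1e-9)

    def test_bruteforce_length_cap(self):
        h = _history([1] + [0] * 14)
        with pytest.raises(ValueError, match="too long"):
            brute_force_loglik(h, _covariates(15, flat=True), TransitionParams())


class TestFitMultistate:
    def test_fit_is_deterministic_given_seed(self, small_colony):
        from conftest import filtered_tables

        histories, females, _ = filtered_tables(small_colony)
        design = build_design(histories, females,
                              standardizers=small_colony.standardizers)
        cfg = McmcConfig(n_chains=2, n_burn=50, n_iter=100, thin=2, seed=9)
        a = fit_multistate(design, "linear", cfg)
        b = fit_multistate(design, "linear", cfg)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_posterior_structure(self, small_fit):
        samples, design = small_fit
        assert samples.n_chains == 2
        expected = set(_phi_names("linear", design.n_cohorts)) | {
            "lambda3_N", "sigma_beta", "sigma_theta", "detection_p",
        }
        assert expected <= set(samples.scalar_names())
        # sum-to-zero previous-state effects hold draw-wise
        s = (samples.draws["lambda3_F"] + samples.draws["lambda3_B"]
             + samples.draws["lambda3_N"])
        assert np.abs(s).max() < 1e-12
        assert (samples.stacked("detection_p") > 0).all()
        assert (samples.stacked("detection_p") < 1).all()
        assert (samples.stacked("sigma_beta") >= 0).all()

    def test_stored_logliks_match_forward_recomputation(self, small_fit):
        from sealrep.multistate import params_from_draw
        from conftest import filtered_tables

        samples, design = small_fit
        ll = samples.draws["loglik_female"]
        for chain, draw in [(0, 0), (1, 37)]:
            tp = params_from_draw(samples, chain, draw)
            logc = np.zeros((design.n_females, design.n_occasions))
            phi = np.array([samples.draws[n][chain, draw]
                            for n in _phi_names("linear", design.n_cohorts)])
            _forward_logc(design.y, design.recruit, design.z_age,
                          design.z_age_sq, design.z_lw, design.z_lw_sq,
                          design.cohort_index, 1, phi, tp.beta, tp.theta,
                          tp.detection_p, logc)
            assert np.allclose(ll[chain, draw], logc.sum(axis=1), atol=1e-9)

    def test_prior_recovered_without_data(self):
        # no females: the sampler must return the prior; KS on lambda5
        # against N(0, 1000) (variance scale) must not reject at alpha=0.01
        T = 5
        design = MultistateDesign(
            female_ids=[], y=np.zeros((0, T), dtype=np.int8),
            recruit=np.zeros(0, dtype=np.int64), z_age=np.zeros((0, T)),
            z_age_sq=np.zeros((0, T)), z_lw=np.zeros(0), z_lw_sq=np.zeros(0),
            cohort_index=np.zeros(0, dtype=np.int64), n_cohorts=5,
            years=np.arange(T), standardizers={},
        )
        cfg = McmcConfig(n_chains=2, n_burn=2000, n_iter=24000, thin=30, seed=3)
        samples = fit_multistate(design, "linear", cfg)
        lam5 = samples.stacked("lambda5")
        ks = stats.kstest(lam5, "norm", args=(0.0, math.sqrt(1000.0)))
        assert ks.pvalue > 0.01
        p = samples.stacked("detection_p")
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestTransitionSummary:
    def _point_mass_samples(self):
        from sealrep.multistate import PosteriorSamples

        tp = TransitionParams.from_transition_rates(0.779, 0.861, 0.878)
        const = lambda v: np.full((2, 20), v)
        draws = {
            "mu": const(tp.mu), "lambda1": const(0.0), "lambda2": const(0.0),
            "lambda3_F": const(tp.lambda3[0]), "lambda3_B": const(tp.lambda3[1]),
            "lambda3_N": const(tp.lambda3[2]), "detection_p": const(0.975),
            "sigma_beta": const(1.0), "sigma_theta": const(1.0),
        }
        return PosteriorSamples(draws=draws, variant="null", n_chains=2,
                                n_burn=0, thin=1)

    def test_degenerate_posterior(self):
        table = transition_summary(self._point_mass_samples())
        assert table.loc["psi_BB", "mean"] == pytest.approx(0.861)
        assert table.loc["psi_BB", "sd"] == 0.0
        for q in ("q2.5", "q50", "q97.5"):
            assert table.loc["psi_NB", q] == pytest.approx(0.878)

    def test_quantiles_match_order_statistics(self):
        from sealrep.multistate import PosteriorSamples

        rng = np.random.default_rng(4)
        u = rng.uniform(0, 1, 3000)
        logits = np.log(u / (1 - u)).reshape(2, 1500)
        zeros = np.zeros_like(logits)
        draws = {"mu": logits, "lambda1": zeros, "lambda2": zeros,
                 "lambda3_F": zeros, "lambda3_B": zeros, "lambda3_N": zeros}
        s = PosteriorSamples(draws=draws, variant="null", n_chains=2,
                             n_burn=0, thin=1)
        table = transition_summary(s)
        for q, level in (("q2.5", 0.025), ("q50", 0.5), ("q97.5", 0.975)):
            assert table.loc["psi_BB", q] == pytest.approx(
                np.quantile(u, level), abs=1e-12
            )
        assert table.loc["psi_BB", "mean"] == pytest.approx(u.mean(), abs=1e-12)
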
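import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bimhmm import (
    IndividualEffects,
    IntegrationConfig,
    SubjectRecord,
    TrialDesign,
    emission_logpdf,
    fit,
    forward_loglik_conditional,
    individual_parameters,
    marginal_logliks,
    ofv,
    reference_parameters,
    simulate_subject,
    simulate_trial,
    viterbi_path,
)
from helpers import enum_loglik, enum_viterbi


def make_subject(pop, T, seed, trt=0, miss_fev1=(), duration=None):
    design = TrialDesign.weekly(n_per_arm=1, duration=duration or T)
    rng = np.random.default_rng(seed)
    rec = simulate_subject(pop, design, trt, rng, subject_id=1)
    if miss_fev1:
        obs = rec.obs_fev1.copy()
        obs[list(miss_fev1)] = False
        rec = SubjectRecord(
            subject_id=1, trt=trt, times=rec.times,
            y_fev1=np.where(obs, rec.y_fev1, np.nan), y_pro=rec.y_pro,
            obs_fev1=obs, obs_pro=rec.obs_pro,
        )
    return rec


class TestForwardAlgorithm:
    @pytest.mark.parametrize("seed,T,trt,miss", [
        (0, 1, 0, ()),
        (1, 4, 0, ()),
        (2, 8, 1, ()),
        (3, 8, 0, (0, 3, 5)),
        (4, 6, 1, (1, 2, 3, 4)),
    ])
    def test_matches_exhaustive_enumeration(self, ref_pop, seed, T, trt, miss):
        sub = make_subject(ref_pop, T, seed, trt, miss)
        rng = np.random.default_rng(100 + seed)
        eta = IndividualEffects.draw(ref_pop, rng)
        ours = forward_loglik_conditional(sub, eta, ref_pop)
        oracle = enum_loglik(ref_pop, eta, sub)
        assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-10)

    @given(
        seed=st.integers(0, 10_000),
        T=st.integers(1, 6),
        trt=st.integers(0, 1),
        pi_re=st.floats(0.02, 0.8),
        pi_er=st.floats(0.02, 0.8),
        rho=st.floats(-0.9, 0.9),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_enumeration_over_random_parameters(self, seed, T, trt, pi_re, pi_er, rho):
        pop = reference_parameters().replace(theta_pi_re=pi_re, theta_pi_er=pi_er,
                                             rho_r=rho, rho_e=-rho)
        sub = make_subject(pop, T, seed, trt)
        eta = IndividualEffects.draw(pop, np.random.default_rng(seed + 1))
        assert forward_loglik_conditional(sub, eta, pop) == pytest.approx(
            enum_loglik(pop, eta, sub), rel=1e-10, abs=1e-10
        )

    def test_single_observation_closed_form(self, ref_pop, zero_eta):
        sub = make_subject(ref_pop, 1, 42)
        indiv = individual_parameters(ref_pop, zero_eta, 0)
        e_r = np.exp(emission_logpdf(sub.y_fev1[0], sub.y_pro[0], "R", indiv, ref_pop, 0.0))
        e_e = np.exp(emission_logpdf(sub.y_fev1[0], sub.y_pro[0], "E", indiv, ref_pop, 0.0))
        expected = np.log(0.9 * e_r + 0.1 * e_e)
        assert forward_loglik_conditional(sub, zero_eta, ref_pop) == pytest.approx(expected)

    def test_indistinguishable_states_ignore_transitions(self, ref_pop, zero_eta):
        """When both states share means and correlation the chain drops out:
        the log-likelihood is the plain sum of emission log-densities."""
        pop = ref_pop.replace(theta_fev1_e=0.0, theta_pro_e=1e-300, rho_e=ref_pop.rho_r)
        sub = make_subject(pop, 10, 7)
        indiv = individual_parameters(pop, zero_eta, 0)
        expected = sum(
            emission_logpdf(sub.y_fev1[j], sub.y_pro[j], "R", indiv, pop, sub.times[j])
            for j in range(10)
        )
        for alt in (pop, pop.replace(theta_pi_re=0.4, theta_pi_er=0.6)):
            assert forward_loglik_conditional(sub, zero_eta, alt) == pytest.approx(expected)

    def test_relabeling_states_preserves_likelihood(self, ref_pop, zero_eta):
        """Swapping the state labels together with all state-indexed
        parameters leaves the likelihood unchanged (placebo arm, no
        placebo time-course so the swap is expressible)."""
        pop = ref_pop.replace(pe=1e-12, slp=0.0)
        sub = make_subject(pop, 12, 19)
        swapped = pop.replace(
            theta_fev1_r=pop.theta_fev1_r - pop.theta_fev1_e,
            theta_fev1_e=-pop.theta_fev1_e,
            theta_pro_r=pop.theta_pro_r + pop.theta_pro_e,
            theta_pro_e=-pop.theta_pro_e,
            init=1.0 - pop.init,
            theta_pi_re=pop.theta_pi_er,
            theta_pi_er=pop.theta_pi_re,
            rho_r=pop.rho_e,
            rho_e=pop.rho_r,
        )
        a = forward_loglik_conditional(sub, zero_eta, pop)
        b = forward_loglik_conditional(sub, zero_eta, swapped)
        assert a == pytest.approx(b, rel=1e-10)

    def test_fev1_missing_row_contributes_univariate_pro(self, ref_pop, zero_eta):
        sub = make_subject(ref_pop, 1, 13, miss_fev1=(0,))
        indiv = individual_parameters(ref_pop, zero_eta, 0)
        e_r = np.exp(emission_logpdf(None, sub.y_pro[0], "R", indiv, ref_pop, 0.0))
        e_e = np.exp(emission_logpdf(None, sub.y_pro[0], "E", indiv, ref_pop, 0.0))
        assert forward_loglik_conditional(sub, zero_eta, ref_pop) == pytest.approx(
            np.log(0.9 * e_r + 0.1 * e_e)
        )

    def test_agrees_with_hmmlearn_in_degenerate_case(self, ref_pop):
        """With no placebo time course the conditional model at eta = 0 is a
        plain Gaussian HMM; cross-check the forward likelihood against
        hmmlearn's scorer."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        pop = ref_pop.replace(pe=1e-12)
        indiv = individual_parameters(pop, IndividualEffects.zero(), 0)
        model = hmm.GaussianHMM(n_components=2, covariance_type="full", init_params="")
        model.startprob_ = np.array([0.9, 0.1])
        model.transmat_ = np.array([[0.95, 0.05], [0.15, 0.85]])
        model.means_ = np.array([
            [indiv.fev1_r, indiv.pro_r_of_t(0.0)],
            [indiv.fev1_e, indiv.pro_e_of_t(0.0)],
        ])
        s = np.sqrt([pop.sigma2_fev1, pop.sigma2_pro])
        off_r = pop.rho_r * s[0] * s[1]
        off_e = pop.rho_e * s[0] * s[1]
        model.covars_ = np.array([
            [[s[0] ** 2, off_r], [off_r, s[1] ** 2]],
            [[s[0] ** 2, off_e], [off_e, s[1] ** 2]],
        ])
        sub = make_subject(pop, 30, 23)
        ours = forward_loglik_conditional(sub, None, pop)
        theirs = model.score(np.column_stack([sub.y_fev1, sub.y_pro]))
        assert ours == pytest.approx(theirs, rel=1e-10)


class TestViterbi:
    @pytest.mark.parametrize("seed,T", [(0, 10), (5, 10), (9, 8)])
    def test_matches_exhaustive_argmax(self, ref_pop, seed, T):
        sub = make_subject(ref_pop, T, seed)
        eta = IndividualEffects.draw(ref_pop, np.random.default_rng(seed))
        path, lj = viterbi_path(sub, eta, ref_pop)
        opath, olj = enum_viterbi(ref_pop, eta, sub)
        assert lj == pytest.approx(olj, rel=1e-10)
        np.testing.assert_array_equal(path, opath)

    def test_dominant_emissions_give_pointwise_argmax(self, ref_pop, zero_eta):
        # essentially noiseless observations: the path follows the data
        pop = ref_pop.replace(sigma2_fev1=1e-6, sigma2_pro=1e-6)
        sub = make_subject(pop, 20, 3)
        path, _ = viterbi_path(sub, zero_eta, pop)
        np.testing.assert_array_equal(path, sub.true_states)

    def test_path_beats_random_paths(self, ref_pop, zero_eta):
        sub = make_subject(ref_pop, 15, 8)
        _, lj = viterbi_path(sub, zero_eta, ref_pop)
        rng = np.random.default_rng(0)
        indiv = individual_parameters(ref_pop, zero_eta, 0)
        from bimhmm import initial_state_prob, transition_matrix

        log_init = np.log([initial_state_prob(ref_pop), 1 - initial_state_prob(ref_pop)])
        log_a = np.log(transition_matrix(ref_pop, 0.0, 0))
        for _ in range(1000):
            seq = rng.integers(0, 2, size=15)
            lp = log_init[seq[0]] + sum(log_a[seq[j - 1], seq[j]] for j in range(1, 15))
            lp += sum(
                emission_logpdf(sub.y_fev1[j], sub.y_pro[j], int(seq[j]), indiv, ref_pop, sub.times[j])
                for j in range(15)
            )
            assert lj >= lp - 1e-9


class TestMarginalization:
    def test_degenerate_prior_reduces_to_conditional(self, ref_pop):
        pop = ref_pop.replace(
            omega2_fev1_r=0, omega2_fev1_e=0, omega2_pro_r=0, omega2_pro_e=0, omega2_pi_re=0
        )
        design = TrialDesign.weekly(n_per_arm=4, duration=10)
        data = simulate_trial(pop, design, seed=21)
        marg = marginal_logliks(data, pop)
        cond = [forward_loglik_conditional(s, None, pop) for s in data.subjects()]
        np.testing.assert_allclose(marg, cond, rtol=0, atol=1e-12)

    @pytest.fixture
    def one_dim_setup(self, ref_pop):
        # only the transition random effect active
        pop = ref_pop.replace(omega2_fev1_r=0, omega2_fev1_e=0, omega2_pro_r=0, omega2_pro_e=0)
        design = TrialDesign.weekly(n_per_arm=5, duration=25)
        return pop, simulate_trial(pop, design, seed=31)

    def test_quadrature_matches_dense_trapezoid(self, one_dim_setup):
        pop, data = one_dim_setup
        quad_ll = marginal_logliks(data, pop, IntegrationConfig(method="quadrature"))
        # brute-force trapezoid over eta in [-6 sd, 6 sd]
        from bimhmm.inference import _subject_arrays
        from bimhmm import _kernels

        sd = np.sqrt(pop.omega2_pi_re)
        grid = np.linspace(-6 * sd, 6 * sd, 4001)
        p = pop.to_vector()
        for i, sub in enumerate(data.subjects()):
            yf, yp, obf, obp, times, trt = _subject_arrays(sub)
            etas = np.zeros((grid.size, 5))
            etas[:, 4] = grid
            cond = np.asarray(
                _kernels.conditional_loglik_many(yf, yp, obf, obp, times, trt, p, etas)
            )
            prior = -0.5 * np.log(2 * np.pi * pop.omega2_pi_re) - 0.5 * grid**2 / pop.omega2_pi_re
            vals = np.exp(cond + prior - cond.max())
            oracle = cond.max() + np.log(np.trapezoid(vals, grid))
            assert quad_ll[i] == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    def test_laplace_close_to_quadrature(self, one_dim_setup):
        pop, data = one_dim_setup
        lap = marginal_logliks(data, pop, IntegrationConfig(method="laplace"))
        quad_ll = marginal_logliks(data, pop, IntegrationConfig(method="quadrature"))
        np.testing.assert_allclose(lap, quad_ll, atol=0.2)

    def test_importance_sampling_consistent_with_quadrature(self, one_dim_setup):
        pop, data = one_dim_setup
        quad_ll = marginal_logliks(data, pop, IntegrationConfig(method="quadrature"))
        mc, se = marginal_logliks(
            data, pop, IntegrationConfig(method="mcis", mc_samples=2000, seed=1), return_se=True
        )
        assert np.all(np.abs(mc - quad_ll) < 5 * np.maximum(se, 1e-4))
        # doubling the sample count moves the estimate by less than its noise
        mc2 = marginal_logliks(data, pop, IntegrationConfig(method="mcis", mc_samples=4000, seed=2))
        assert np.all(np.abs(mc2 - mc) < 6 * np.maximum(se, 1e-4))

    def test_mcis_deterministic_given_seed(self, one_dim_setup):
        pop, data = one_dim_setup
        cfg = IntegrationConfig(method="mcis", mc_samples=200, seed=7)
        np.testing.assert_array_equal(
            marginal_logliks(data, pop, cfg), marginal_logliks(data, pop, cfg)
        )


class TestFit:
    def test_ofv_is_sum_of_iofv(self, ref_pop, tiny_trial):
        total, iofv = ofv(tiny_trial, ref_pop)
        assert total == pytest.approx(iofv.sum(), abs=1e-6)
        assert np.all(np.isfinite(iofv))

    def test_descent_from_truth_start(self, ref_pop, tiny_trial):
        start_ofv, _ = ofv(tiny_trial, ref_pop)
        res = fit(tiny_trial, ref_pop, free=["theta_pi_re", "theta_pi_er", "slp"])
        assert res.ofv <= start_ofv + 1e-6
        assert res.converged

    def test_fit_deterministic(self, ref_pop, tiny_trial):
        kw = dict(free=["theta_fev1_r", "sigma2_fev1"])
        a = fit(tiny_trial, ref_pop, **kw)
        b = fit(tiny_trial, ref_pop, **kw)
        assert a.ofv == b.ofv
        assert a.estimates.to_dict() == b.estimates.to_dict()

    def test_full_model_never_worse_than_reduced(self, ref_pop):
        """Nested-model ordering on uncorrelated-truth data: estimating the
        correlations cannot fit worse than fixing them at the true zero."""
        pop = ref_pop.replace(rho_r=1e-12, rho_e=1e-12)
        design = TrialDesign.weekly(n_per_arm=8, duration=15)
        data = simulate_trial(pop, design, seed=41)
        emission_free = ["theta_fev1_r", "theta_pro_r", "sigma2_fev1", "sigma2_pro"]
        full = fit(data, pop, free=emission_free + ["rho_r", "rho_e"])
        reduced = fit(data, pop, free=emission_free)
        assert full.ofv <= reduced.ofv + 0.1

    def test_unknown_free_name_rejected(self, ref_pop, tiny_trial):
        with pytest.raises(ValueError, match="unknown parameter"):
            fit(tiny_trial, ref_pop, free=["not_a_parameter"])

    def test_recovery_without_random_effects(self, ref_pop):
        """Near-noiseless sanity run: with all variability off except tiny
        residuals, the remission FEV1 mode is recovered essentially exactly."""
        pop = ref_pop.replace(
            omega2_fev1_r=0, omega2_fev1_e=0, omega2_pro_r=0, omega2_pro_e=0,
            omega2_pi_re=0, sigma2_fev1=1e-4, sigma2_pro=1e-4,
        )
        design = TrialDesign.weekly(n_per_arm=10, duration=10)
        data = simulate_trial(pop, design, seed=51)
        res = fit(data, pop.replace(theta_fev1_r=1.9), free=["theta_fev1_r"])
        assert res.estimates.theta_fev1_r == pytest.approx(2.0, abs=1e-2)
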
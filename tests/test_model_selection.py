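import numpy as np
import pytest
from scipy import special
from scipy.special import logsumexp

import fpinfer as fp
from fpinfer.model_selection import numerical_hessian, proposal_covariance


def quadrature_log_evidence_m1(data: fp.BinnedData, priors: fp.PriorConfig,
                               n: int = 600, tau_max: float = 250.0, L_max: float = 60.0) -> float:
    """Brute-force oracle: midpoint-rule 2-D integral of F(tau, L) for M=1."""
    taus = (np.arange(n) + 0.5) * tau_max / n
    Ls = (np.arange(n) + 0.5) * L_max / n
    T, L = np.meshgrid(taus, Ls, indexing="ij")
    occ = np.nonzero(data.counts > 0)[0]
    ll = np.zeros_like(T)
    for k in occ:
        p = special.gammainc(L, data.edges[k + 1] / T) - special.gammainc(L, data.edges[k] / T)
        ll += data.counts[k] * np.log(np.clip(p, 1e-300, None))
    lp = -T / priors.Z_tau - np.log(priors.Z_tau) - L / priors.Z_L - np.log(priors.Z_L)
    return float(logsumexp(ll + lp) + np.log(tau_max / n * L_max / n))


class TestLogPrior:
    def test_value_at_prior_scales(self):
        priors = fp.PriorConfig()
        m = fp.FPModel(tau=[20.0], L=[20.0])
        assert fp.log_prior(m, priors) == pytest.approx(-2 - 2 * np.log(20.0), rel=1e-12)

    def test_outside_flux_support_is_neg_inf(self):
        priors = fp.PriorConfig(Z_x=10.0)
        m = fp.FPModel(tau=[1.0, 1.0], L=[1.0, 1.0], x=[11.0])
        assert fp.log_prior(m, priors) == -np.inf

    def test_normalizes_for_single_path(self):
        # grid quadrature of exp(log_prior) over (tau, L)
        priors = fp.PriorConfig()
        n, hi = 2000, 300.0
        g = (np.arange(n) + 0.5) * hi / n
        T, L = np.meshgrid(g, g, indexing="ij")
        vals = np.exp(-T / 20 - L / 20) / 400.0
        integral = vals.sum() * (hi / n) ** 2
        assert integral == pytest.approx(1.0, abs=1e-3)


class TestProposalCovariance:
    def test_hessian_of_quadratic_is_exact(self):
        A = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 3.0]])

        def quad(x):
            return -0.5 * x @ A @ x

        H = numerical_hessian(quad, np.array([0.3, -0.2, 1.0]), np.full(3, 1e-4))
        np.testing.assert_allclose(-H, A, atol=1e-5)

    def test_matches_full_fisher_information_for_gamma_fit(self):
        # var(tau-hat) from inverting the 2x2 Gamma Fisher matrix:
        # I = [[psi'(L), 1/tau], [1/tau, L/tau^2]] per event
        tau0, N = 10.0, 20_000
        times = fp.generate_dataset(fp.FPModel(tau=[tau0], L=[1.0]), N, 0.05, seed=31)
        data = fp.bin_isi(times, 0.05)
        fit = fp.fit_mle(data, 1, config=fp.FitConfig(seed=2))
        cov = proposal_covariance(fit, data)
        tau_hat, L_hat = fit.model.tau[0], fit.model.L[0]
        I = np.array(
            [[L_hat / tau_hat**2, 1 / tau_hat], [1 / tau_hat, special.polygamma(1, L_hat)]]
        )
        expected = np.linalg.inv(N * I)
        assert cov[0, 0] == pytest.approx(expected[0, 0], rel=0.2)
        assert cov[1, 1] == pytest.approx(expected[1, 1], rel=0.2)

    def test_boundary_path_gets_block_diagonal_variances(self, two_path_fit):
        data, fit2 = two_path_fit
        # force path 2 to be treated as trivial
        forced = fp.FitResult(
            model=fit2.model,
            log_f=fit2.log_f,
            log_lik=fit2.log_lik,
            at_boundary=np.array([False, True]),
            starts_used=fit2.starts_used,
        )
        cfg = fp.ISConfig()
        cov = proposal_covariance(forced, data, cfg)
        # trivial path's coords (x2, tau2, L2) = indices 2, 3, 4
        np.testing.assert_allclose(np.diag(cov)[2:], [cfg.alpha_x**2, cfg.alpha_tau_sq, cfg.alpha_L_sq])
        off = cov[2:, :2]
        np.testing.assert_array_equal(off, np.zeros_like(off))
        assert cov[2, 3] == 0 and cov[2, 4] == 0 and cov[3, 4] == 0
        # curvature block for the surviving path is positive definite
        assert np.all(np.linalg.eigvalsh(cov[:2, :2]) > 0)


class TestLogMarginalLikelihood:
    def test_matches_dense_quadrature_on_tiny_data(self, tiny_exponentialish_data):
        data = tiny_exponentialish_data
        priors = fp.PriorConfig()
        oracle = quadrature_log_evidence_m1(data, priors)
        fit = fp.fit_mle(data, 1, priors)
        ev = fp.log_marginal_likelihood(data, 1, priors, fp.ISConfig(n_samples=50_000, seed=1), fit)
        err = max(ev.err_lo, ev.err_hi)
        assert abs(ev.log_evidence - oracle) < 2 * np.hypot(err, 0.01)

    def test_seed_scatter_consistent_with_reported_error(self, tiny_exponentialish_data):
        data = tiny_exponentialish_data
        fit = fp.fit_mle(data, 1)
        evs = [
            fp.log_marginal_likelihood(data, 1, cfg=fp.ISConfig(n_samples=20_000, seed=s), fit=fit)
            for s in range(10)
        ]
        vals = np.array([e.log_evidence for e in evs])
        typical_err = np.mean([max(e.err_lo, e.err_hi) for e in evs])
        # empirical scatter should match the reported error bar to a factor ~2.5
        assert vals.std() < 2.5 * typical_err
        assert vals.std() > typical_err / 2.5

    def test_deterministic_given_seed(self, tiny_exponentialish_data):
        data = tiny_exponentialish_data
        fit = fp.fit_mle(data, 1)
        cfg = fp.ISConfig(n_samples=5_000, seed=4)
        a = fp.log_marginal_likelihood(data, 1, cfg=cfg, fit=fit)
        b = fp.log_marginal_likelihood(data, 1, cfg=cfg, fit=fit)
        assert a.log_evidence == b.log_evidence

    def test_boundary_order_scores_close_to_nested_order(self, tiny_exponentialish_data):
        # scoring an M=2 model whose extra path is pinned at zero flux
        # exercises the boundary-covariance route end to end; the evidence
        # must stay finite and cannot beat the nested M=1 evidence by more
        # than the relabeling factor ln(1!) = 0 plus Monte-Carlo error
        data = tiny_exponentialish_data
        priors = fp.PriorConfig()
        fit1 = fp.fit_mle(data, 1, priors)
        theta2 = np.concatenate([fit1.model.theta, [0.0, 20.0, 20.0]])
        m2 = fp.FPModel.from_theta(theta2)
        fit2 = fp.FitResult(
            model=m2,
            log_f=fp.log_objective(data, m2, priors),
            log_lik=fit1.log_lik,
            at_boundary=np.array([False, True]),
            starts_used=1,
        )
        ev2 = fp.log_marginal_likelihood(data, 2, priors, fp.ISConfig(n_samples=50_000, seed=2), fit2)
        ev1 = fp.log_marginal_likelihood(data, 1, priors, fp.ISConfig(n_samples=50_000, seed=2), fit1)
        assert np.isfinite(ev2.log_evidence)
        assert ev2.log_evidence < ev1.log_evidence + 1.0


class TestSelectModel:
    def test_occam_penalty_on_single_path_data(self):
        times = fp.generate_dataset(fp.FPModel(tau=[5.0], L=[2.0]), 1000, 0.1, seed=8)
        res = fp.select_model(
            times, 0.1, 2,
            fit_cfg=fp.FitConfig(seed=1),
            is_cfg=fp.ISConfig(n_samples=10_000, seed=2),
        )
        ev1, ev2 = res.per_M[1][0], res.per_M[2][0]
        combined = np.hypot(max(ev1.err_lo, ev1.err_hi), max(ev2.err_lo, ev2.err_hi))
        assert ev2.log_evidence <= ev1.log_evidence + max(combined, 0.5)

    def test_two_path_data_selects_two_paths(self, two_path_sample):
        res = fp.select_model(
            two_path_sample, 0.1, 3,
            fit_cfg=fp.FitConfig(seed=1),
            is_cfg=fp.ISConfig(n_samples=5_000, seed=2),
        )
        assert res.best_M == 2
        assert not res.failures

    def test_multi_with_single_dataset_equals_single(self, tiny_exponentialish_data):
        times = fp.generate_dataset(fp.FPModel(tau=[5.0], L=[2.0]), 200, 0.5, seed=12)
        fit_cfg, is_cfg = fp.FitConfig(seed=3), fp.ISConfig(n_samples=5_000, seed=4)
        single = fp.select_model(times, 0.5, 2, fit_cfg=fit_cfg, is_cfg=is_cfg)
        multi = fp.select_model_multi([(1.0, times)], 0.5, 2, fit_cfg=fit_cfg, is_cfg=is_cfg)
        for M in (1, 2):
            assert multi.totals[M][0] == pytest.approx(single.per_M[M][0].log_evidence)
        assert multi.best_M == single.best_M

    def test_additivity_over_identical_datasets(self):
        times = fp.generate_dataset(fp.FPModel(tau=[5.0], L=[2.0]), 200, 0.5, seed=14)
        fit_cfg, is_cfg = fp.FitConfig(seed=3), fp.ISConfig(n_samples=10_000, seed=4)
        single = fp.select_model(times, 0.5, 1, fit_cfg=fit_cfg, is_cfg=is_cfg)
        multi = fp.select_model_multi(
            [(1.0, times), (2.0, times)], 0.5, 1, fit_cfg=fit_cfg, is_cfg=is_cfg
        )
        ev = single.per_M[1][0]
        combined = 3 * np.hypot(max(ev.err_lo, ev.err_hi), max(ev.err_lo, ev.err_hi))
        assert multi.totals[1][0] == pytest.approx(2 * ev.log_evidence, abs=max(combined, 0.05))
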
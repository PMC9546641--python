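"""Unit and property tests for the variational Bayesian GMM core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from vmgcaps import vbgmm
from vmgcaps.vbgmm import (InvalidInputError, NumericalDomainError,
                           PriorHyperparams, Responsibilities,
                           VariationalState, compute_expected_stats,
                           compute_log_rho, default_priors, elbo, elbo_terms,
                           fit, init_state, m_step, responsibilities,
                           sufficient_stats)

from conftest import diag_priors


# ---------------------------------------------------------------------------
# independent scalar oracle for the seven ELBO terms (loops, no vectorization)
# ---------------------------------------------------------------------------

def _oracle_elbo_1d(data, r, state, priors):
    """Term-by-term ELBO for D=1, written directly from the densities."""
    N, K = r.shape
    x = data[:, 0]
    a, b, m, W, nu = (state.alpha, state.beta, state.m[:, 0],
                      state.W[:, 0], state.nu)
    a0, b0, mu0, W0, nu0 = (priors.alpha0, priors.beta0, priors.mu0[0],
                            priors.W0[0], priors.nu0)

    def log_B(w, v):
        return -0.5 * v * np.log(w) - 0.5 * v * np.log(2.0) \
            - special.gammaln(v / 2.0)

    loglam = [special.digamma(nu[k] / 2.0) + np.log(2.0) + np.log(W[k])
              for k in range(K)]
    logpi = [special.digamma(a[k]) - special.digamma(a.sum())
             for k in range(K)]
    y = [sum(r[n, k] for n in range(N)) for k in range(K)]
    xbar = [sum(r[n, k] * x[n] for n in range(N)) / y[k] if y[k] > 0 else mu0
            for k in range(K)]
    S = [sum(r[n, k] * (x[n] - xbar[k]) ** 2 for n in range(N)) / y[k]
         if y[k] > 0 else 0.0 for k in range(K)]

    t1 = 0.5 * sum(y[k] * (loglam[k] - 1.0 / b[k] - nu[k] * S[k] * W[k]
                           - nu[k] * (xbar[k] - m[k]) ** 2 * W[k]
                           - np.log(2 * np.pi)) for k in range(K))
    t2 = sum(r[n, k] * logpi[k] for n in range(N) for k in range(K))
    t3 = (special.gammaln(K * a0) - K * special.gammaln(a0)
          + (a0 - 1) * sum(logpi))
    t4 = sum(0.5 * (np.log(b0 / (2 * np.pi)) + loglam[k] - b0 / b[k]
                    - b0 * nu[k] * (m[k] - mu0) ** 2 * W[k])
             + log_B(W0, nu0) + 0.5 * (nu0 - 2) * loglam[k]
             - 0.5 * nu[k] * W[k] / W0 for k in range(K))
    t5 = sum(r[n, k] * np.log(r[n, k]) for n in range(N) for k in range(K)
             if r[n, k] > 0)
    t6 = sum((a[k] - 1) * logpi[k] for k in range(K)) \
        + special.gammaln(a.sum()) - sum(special.gammaln(a[k])
                                         for k in range(K))
    H = [-log_B(W[k], nu[k]) - 0.5 * (nu[k] - 2) * loglam[k] + 0.5 * nu[k]
         for k in range(K)]
    t7 = sum(0.5 * loglam[k] + 0.5 * np.log(b[k] / (2 * np.pi)) - 0.5 - H[k]
             for k in range(K))
    return t1 + t2 + t3 + t4 - t5 - t6 - t7


# ---------------------------------------------------------------------------
# init_state
# ---------------------------------------------------------------------------

class TestInitState:
    def test_single_component_forces_unit_responsibility(self, rng):
        data = rng.normal(size=(7, 2))
        _, resp = init_state(data, 1, diag_priors(2, K=1), seed=3)
        np.testing.assert_array_equal(resp.r, np.ones((7, 1)))

    def test_seeded_determinism_is_bitwise(self, rng):
        data = rng.normal(size=(9, 3))
        pri = diag_priors(3)
        s1, r1 = init_state(data, 3, pri, seed=11)
        s2, r2 = init_state(data, 3, pri, seed=11)
        assert np.array_equal(r1.r, r2.r)
        for f in ("alpha", "beta", "m", "W", "nu"):
            assert np.array_equal(getattr(s1, f), getattr(s2, f))

    def test_rows_sum_to_one(self, rng):
        data = rng.normal(size=(5, 2))
        _, resp = init_state(data, 3, diag_priors(2, K=3), seed=0,
                             method="random")
        np.testing.assert_allclose(resp.r.sum(axis=1), 1.0, atol=1e-12)

    def test_nonfinite_data_rejected(self):
        bad = np.array([[np.nan, 0.0]])
        with pytest.raises(InvalidInputError):
            init_state(bad, 1, diag_priors(2, K=1), seed=0)

    def test_more_components_than_points_warns(self, rng):
        data = rng.normal(size=(2, 2))
        with pytest.warns(UserWarning):
            init_state(data, 5, diag_priors(2, K=5), seed=0)


# ---------------------------------------------------------------------------
# expected statistics
# ---------------------------------------------------------------------------

class TestExpectedStats:
    def test_single_component_log_pi_is_zero(self):
        st_ = VariationalState(alpha=np.array([3.7]), beta=np.array([1.0]),
                               m=np.zeros((1, 2)), W=np.ones((1, 2)),
                               nu=np.array([3.0]))
        ex = compute_expected_stats(st_)
        np.testing.assert_allclose(ex.log_pi_tilde, [0.0], atol=1e-15)

    def test_symmetric_dirichlet_digamma_value(self):
        # alpha = (2, 2): psi(2) - psi(4) = -(1/2 + 1/3) = -5/6
        st_ = VariationalState(alpha=np.array([2.0, 2.0]),
                               beta=np.ones(2), m=np.zeros((2, 1)),
                               W=np.ones((2, 1)), nu=np.full(2, 2.0))
        ex = compute_expected_stats(st_)
        np.testing.assert_allclose(ex.log_pi_tilde, [-5.0 / 6.0] * 2,
                                   atol=1e-12)

    def test_scalar_log_lambda_evaluation(self):
        # D=1, nu=3, W=0.5: psi(1.5) + ln 2 + ln 0.5 = psi(1.5)
        st_ = VariationalState(alpha=np.array([1.0]), beta=np.array([1.0]),
                               m=np.zeros((1, 1)), W=np.array([[0.5]]),
                               nu=np.array([3.0]))
        ex = compute_expected_stats(st_)
        np.testing.assert_allclose(ex.log_lambda_tilde,
                                   [special.digamma(1.5)], atol=1e-12)

    def test_nonpositive_W_raises(self):
        st_ = VariationalState(alpha=np.array([1.0]), beta=np.array([1.0]),
                               m=np.zeros((1, 1)), W=np.array([[-1.0]]),
                               nu=np.array([3.0]))
        with pytest.raises(NumericalDomainError):
            compute_expected_stats(st_)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

class TestLogRhoAndResponsibilities:
    def test_identical_components_give_identical_columns(self, rng):
        st_ = VariationalState(alpha=np.full(2, 0.5), beta=np.ones(2),
                               m=np.zeros((2, 3)), W=np.ones((2, 3)),
                               nu=np.full(2, 4.0))
        lr = compute_log_rho(st_, rng.normal(size=(6, 3)))
        np.testing.assert_allclose(lr[:, 0], lr[:, 1], atol=1e-12)

    def test_row_shift_invariance_of_normalization(self, rng):
        lr = rng.normal(size=(4, 3))
        r1 = responsibilities(lr)
        r2 = responsibilities(lr + 7.5)
        np.testing.assert_allclose(r1.r, r2.r, atol=1e-12)

    def test_scalar_formula_evaluation(self):
        # D=1, x=0, m=0, beta=1, nu=2, W=1, alpha=(1,)
        st_ = VariationalState(alpha=np.array([1.0]), beta=np.array([1.0]),
                               m=np.zeros((1, 1)), W=np.array([[1.0]]),
                               nu=np.array([2.0]))
        lr = compute_log_rho(st_, np.array([[0.0]]))
        loglam = special.digamma(1.0) + np.log(2.0)
        expected = 0.0 + 0.5 * loglam - 0.5 * np.log(2 * np.pi) \
            - 0.5 * (1.0 + 0.0)
        np.testing.assert_allclose(lr, [[expected]], atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        st_ = VariationalState(alpha=np.array([1.0]), beta=np.array([1.0]),
                               m=np.zeros((1, 2)), W=np.ones((1, 2)),
                               nu=np.array([3.0]))
        with pytest.raises(InvalidInputError):
            compute_log_rho(st_, rng.normal(size=(3, 5)))

    @pytest.mark.parametrize("row,expected", [
        ((0.0, np.log(3.0)), (0.25, 0.75)),
        ((1.0, 1.0, 1.0), (1 / 3, 1 / 3, 1 / 3)),
    ])
    def test_known_normalizations(self, row, expected):
        r = responsibilities(np.array([row]))
        np.testing.assert_allclose(r.r, [expected], atol=1e-12)

    def test_single_component_is_all_ones(self):
        r = responsibilities(np.array([[-50.0], [3.0]]))
        np.testing.assert_array_equal(r.r, np.ones((2, 1)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 30), st.integers(1, 5), st.integers(0, 1000))
    def test_rows_always_sum_to_one(self, n, k, seed):
        lr = np.random.default_rng(seed).normal(scale=50.0, size=(n, k))
        r = responsibilities(lr)
        assert np.all(r.r >= 0)
        np.testing.assert_allclose(r.r.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# sufficient statistics and M-step
# ---------------------------------------------------------------------------

class TestStatsAndMStep:
    def test_one_hot_gives_sample_moments(self, rng):
        data = rng.normal(size=(20, 3))
        r = np.zeros((20, 2))
        r[:, 0] = 1.0
        stats = sufficient_stats(data, Responsibilities(r))
        assert stats.y[0] == pytest.approx(20)
        np.testing.assert_allclose(stats.xbar[0], data.mean(axis=0))
        ml_cov = np.cov(data.T, bias=True)
        np.testing.assert_allclose(stats.S[0], ml_cov, atol=1e-10)

    def test_counts_sum_to_n(self, rng):
        data = rng.normal(size=(13, 2))
        r = np.random.default_rng(0).dirichlet(np.ones(4), size=13)
        stats = sufficient_stats(data, Responsibilities(r))
        assert stats.y.sum() == pytest.approx(13, abs=1e-10)

    def test_hand_computed_two_point_fixture(self):
        data = np.array([[0.0], [2.0]])
        r = np.full((2, 2), 0.5)
        stats = sufficient_stats(data, Responsibilities(r))
        np.testing.assert_allclose(stats.y, [1.0, 1.0])
        np.testing.assert_allclose(stats.xbar, [[1.0], [1.0]])
        np.testing.assert_allclose(stats.S[:, 0, 0], [1.0, 1.0])

    def test_empty_component_posterior_equals_prior(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]])
        r = np.zeros((2, 2))
        r[:, 0] = 1.0
        pri = diag_priors(2)
        state = m_step(pri, sufficient_stats(data, Responsibilities(r),
                                             mu0=pri.mu0))
        assert state.alpha[1] == pytest.approx(pri.alpha0)
        assert state.beta[1] == pytest.approx(pri.beta0)
        np.testing.assert_allclose(state.m[1], pri.mu0)
        np.testing.assert_allclose(state.W[1], pri.W0)
        assert state.nu[1] == pytest.approx(pri.nu0)

    def test_hand_computed_mean_update(self):
        # D=1, beta0=1, mu0=0, y=4, xbar=2 -> beta=5, m=1.6
        pri = diag_priors(1, K=1, alpha0=0.5)
        stats = vbgmm.SufficientStats(y=np.array([4.0]),
                                      xbar=np.array([[2.0]]),
                                      S=np.zeros((1, 1, 1)))
        state = m_step(pri, stats)
        assert state.beta[0] == pytest.approx(5.0)
        assert state.m[0, 0] == pytest.approx(1.6)

    def test_dirichlet_mass_conservation(self, rng):
        data = rng.normal(size=(17, 2))
        pri = diag_priors(2, K=3, alpha0=0.7)
        r = np.random.default_rng(5).dirichlet(np.ones(3), size=17)
        state = m_step(pri, sufficient_stats(data, Responsibilities(r)))
        assert state.alpha.sum() == pytest.approx(3 * 0.7 + 17, abs=1e-10)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

class TestElbo:
    def _fixture(self):
        data = np.array([[-1.0], [0.0], [0.5], [2.0]])
        pri = diag_priors(1)
        r = np.array([[0.9, 0.1], [0.6, 0.4], [0.3, 0.7], [0.05, 0.95]])
        resp = Responsibilities(r)
        state = m_step(pri, sufficient_stats(data, resp, mu0=pri.mu0))
        return data, resp, state, pri

    def test_one_hot_responsibility_entropy_is_zero(self):
        data = np.array([[0.0], [1.0]])
        pri = diag_priors(1)
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        resp = Responsibilities(r)
        state = m_step(pri, sufficient_stats(data, resp, mu0=pri.mu0))
        terms = elbo_terms(data, resp, state, pri)
        assert terms["log_qz"] == 0.0

    def test_four_point_fixture_matches_term_oracle(self):
        data, resp, state, pri = self._fixture()
        assert elbo(data, resp, state, pri) == pytest.approx(
            _oracle_elbo_1d(data, resp.r, state, pri), abs=1e-10)

    def test_terms_sum_to_total(self):
        data, resp, state, pri = self._fixture()
        t = elbo_terms(data, resp, state, pri)
        total = (t["log_px"] + t["log_pz"] + t["log_ppi"]
                 + t["log_pmu_lambda"] - t["log_qz"] - t["log_qpi"]
                 - t["log_qmu_lambda"])
        assert elbo(data, resp, state, pri) == pytest.approx(total)

    def test_e_step_after_m_step_never_decreases_elbo(self, rng):
        data = rng.normal(size=(25, 2))
        pri = diag_priors(2, K=3)
        state, resp = init_state(data, 3, pri, seed=4)
        before = elbo(data, resp, state, pri)
        resp2 = responsibilities(compute_log_rho(state, data))
        state2 = m_step(pri, sufficient_stats(data, resp2, mu0=pri.mu0))
        after = elbo(data, resp2, state2, pri)
        assert after >= before - 1e-8 * abs(after)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_k1_matches_closed_form_normal_wishart(self, rng):
        data = rng.normal(loc=1.5, scale=2.0, size=(40, 1))
        pri = diag_priors(1, K=1, alpha0=1.0)
        res = fit(data, 1, pri, max_iter=3, seed=0)
        N = 40
        xbar = data.mean(axis=0)
        S = ((data - xbar) ** 2).mean(axis=0)
        beta = pri.beta0 + N
        m = (pri.beta0 * pri.mu0 + N * xbar) / beta
        W_inv = 1.0 / pri.W0 + N * S + (pri.beta0 * N / beta) \
            * (xbar - pri.mu0) ** 2
        assert res.state.beta[0] == pytest.approx(beta, abs=1e-10)
        np.testing.assert_allclose(res.state.m[0], m, atol=1e-10)
        np.testing.assert_allclose(1.0 / res.state.W[0], W_inv, atol=1e-10)
        assert res.state.nu[0] == pytest.approx(pri.nu0 + N, abs=1e-10)

    def test_recovers_three_separated_clusters(self, three_cluster_data):
        pts, labels, centers = three_cluster_data
        res = fit(pts, 3, seed=1)
        y = np.sort(res.resp.r.sum(axis=0))
        np.testing.assert_allclose(y, [100, 100, 100], atol=10)
        sample_means = np.array([pts[labels == k].mean(axis=0)
                                 for k in range(3)])
        d = np.linalg.norm(res.state.m[:, None] - sample_means[None],
                           axis=-1)
        # greedy row/col matching is enough at separation 8
        assert sorted(d.min(axis=1).tolist()) == sorted(
            d.min(axis=0).tolist())
        assert d.min(axis=1).max() < 0.1

    def test_max_iter_one_gives_single_trace_entry(self, rng):
        data = rng.normal(size=(12, 2))
        res = fit(data, 2, diag_priors(2), max_iter=1, seed=0)
        assert len(res.elbo_trace) == 1
        assert res.n_iter == 1

    @settings(deadline=None, max_examples=12, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_elbo_trace_is_monotone(self, seed):
        gen = np.random.default_rng(seed)
        n, d, k = int(gen.integers(8, 60)), int(gen.integers(1, 4)), \
            int(gen.integers(1, 4))
        data = gen.normal(scale=3.0, size=(n, d))
        res = fit(data, k, seed=seed, n_init=1)
        tr = np.array(res.elbo_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[1:]))

    def test_no_variance_collapse_on_duplicated_points(self):
        data = np.tile([[2.0, -1.0]], (30, 1))
        res = fit(data, 2, diag_priors(2), seed=0)
        assert np.all(np.isfinite(res.state.W))
        assert np.all(res.state.W > 0)


# ---------------------------------------------------------------------------
# diagonal vs full-matrix mode
# ---------------------------------------------------------------------------

class TestDiagonalFullAgreement:
    def test_modes_agree_when_scatter_is_diagonal(self):
        # scatter of {(+-a, 0), (0, +-b)} around 0 is exactly diagonal
        data = np.array([[3.0, 0.0], [-3.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        r = np.full((4, 1), 1.0)
        resp = Responsibilities(r)
        pri_d = diag_priors(2, K=1, alpha0=1.0)
        pri_f = PriorHyperparams(alpha0=1.0, beta0=1.0, mu0=np.zeros(2),
                                 W0=np.eye(2), nu0=3.0)
        st_d = m_step(pri_d, sufficient_stats(data, resp, mu0=pri_d.mu0))
        st_f = m_step(pri_f, sufficient_stats(data, resp, mu0=pri_f.mu0))
        np.testing.assert_allclose(st_d.W[0], np.diag(st_f.W[0]), atol=1e-12)
        np.testing.assert_allclose(
            compute_log_rho(st_d, data), compute_log_rho(st_f, data),
            atol=1e-12)
        assert elbo(data, resp, st_d, pri_d) == pytest.approx(
            elbo(data, resp, st_f, pri_f), abs=1e-10)


class TestPriorValidation:
    @pytest.mark.parametrize("kw", [
        dict(alpha0=0.0), dict(beta0=-1.0), dict(nu0=0.5),
    ])
    def test_invalid_hyperparameters_rejected(self, kw):
        base = dict(alpha0=1.0, beta0=1.0, mu0=np.zeros(2),
                    W0=np.ones(2), nu0=3.0)
        base.update(kw)
        with pytest.raises(InvalidInputError):
            PriorHyperparams(**base)

    def test_default_priors_satisfy_constraints(self, rng):
        data = rng.normal(size=(10, 3))
        pri = default_priors(data, 4, 3)
        assert pri.alpha0 == pytest.approx(0.25)
        assert pri.nu0 > pri.D - 1
        np.testing.assert_allclose(pri.mu0, data.mean(axis=0))
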
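import numpy as np
import pytest

import agrichoice as ac
from agrichoice.latent import (
    LCLParameters,
    class_membership_probs,
    fit_lcl,
    information_criteria,
    lcl_loglik,
    select_classes,
    wald_joint_test,
)
from agrichoice.mnl import fit_mnl, grouped_design, mnl_loglik
from agrichoice.simulate import ClassSpec, SimulationConfig


def brute_force_lcl_loglik(beta, lam, gd):
    """Independent oracle: explicit per-unit loops, no log-sum-exp."""
    S = beta.shape[0]
    total = 0.0
    for n in range(gd.n_units):
        Z = gd.Z[n]
        eta = [float(lam[s] @ Z) for s in range(S - 1)] + [0.0]
        e = np.exp(eta)
        pi = e / e.sum()
        unit_sum = 0.0
        for s in range(S):
            prod = 1.0
            for g in np.flatnonzero(gd.unit_of_group == n):
                rows = slice(gd.group_ptr[g], gd.group_ptr[g + 1])
                u = gd.X[rows] @ beta[s]
                p = np.exp(u) / np.exp(u).sum()
                prod *= p[gd.chosen[rows]][0]
            unit_sum += pi[s] * prod
        total += np.log(unit_sum)
    return total


def lcl_sim(seed, n_resp=200, n_plots=220, beta=None, shares=(0.5, 0.5),
            lam=None, covars=("gender", "credit")):
    if beta is None:
        beta = np.array(
            [
                [-0.2, -0.3, 1.5, 0.8, 1.2, 0.5, 0.4, 0.0, 0.0],
                [-2.5, 0.1, -1.0, -0.6, 0.2, -1.5, -0.8, 0.0, 0.0],
            ]
        )
    spec = ClassSpec(beta=beta, shares=None if lam is not None else shares,
                     lam=lam, membership_covariates=covars)
    cfg = SimulationConfig(n_respondents=n_resp, n_plots=n_plots,
                           class_spec=spec, rng_seed=seed)
    ds = ac.simulate_choices_lcl(cfg)
    return grouped_design(ds, membership_covariates=covars)


class TestMembershipProbs:
    def test_zero_lambda_uniform(self):
        Z = np.array([[1.0, 0.5]])
        probs = class_membership_probs(np.zeros((2, 2)), Z)
        np.testing.assert_allclose(probs, [[1 / 3, 1 / 3, 1 / 3]])

    def test_log3_closed_form(self):
        Z = np.array([[1.0]])
        lam = np.array([[np.log(3.0)]])
        probs = class_membership_probs(lam, Z)
        np.testing.assert_allclose(probs, [[0.75, 0.25]], atol=1e-12)

    def test_monotone_in_eta(self):
        Z = np.array([[1.0]])
        p_prev = 0.0
        for v in np.linspace(-2, 2, 9):
            p = class_membership_probs(np.array([[v]]), Z)[0, 0]
            assert p > p_prev or v == -2
            p_prev = p

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = class_membership_probs(rng.normal(size=(3, 4)),
                                       rng.normal(size=(10, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestLoglik:
    def test_s1_equals_mnl(self, toy_dataset):
        gd = grouped_design(toy_dataset, membership_covariates=())
        beta = np.random.default_rng(1).normal(scale=0.3, size=(1, gd.p))
        params = LCLParameters(beta=beta, lam=np.zeros((0, 1)))
        ll_mix = lcl_loglik(params, gd)
        ll_mnl, _ = mnl_loglik(beta[0], gd)
        assert ll_mix == pytest.approx(ll_mnl, abs=1e-10)

    def test_identical_betas_ignore_lambda(self):
        gd = lcl_sim(3, n_resp=20, n_plots=22)
        rng = np.random.default_rng(2)
        beta = np.tile(rng.normal(scale=0.3, size=gd.p), (2, 1))
        lls = []
        for _ in range(3):
            lam = rng.normal(size=(1, gd.Z.shape[1]))
            lls.append(lcl_loglik(LCLParameters(beta=beta, lam=lam), gd))
        assert np.ptp(lls) < 1e-10

    def test_brute_force_oracle_tiny(self):
        gd = lcl_sim(4, n_resp=3, n_plots=3)
        rng = np.random.default_rng(5)
        for _ in range(5):
            beta = rng.normal(scale=0.5, size=(2, gd.p))
            lam = rng.normal(scale=0.5, size=(1, gd.Z.shape[1]))
            ll = lcl_loglik(LCLParameters(beta=beta, lam=lam), gd)
            oracle = brute_force_lcl_loglik(beta, lam, gd)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        from agrichoice.latent import _ll_grad, _unit_ptr

        gd = lcl_sim(6, n_resp=15, n_plots=16)
        uptr = _unit_ptr(gd)
        rng = np.random.default_rng(7)
        q = gd.Z.shape[1]
        beta = rng.normal(scale=0.3, size=(2, gd.p))
        lam = rng.normal(scale=0.3, size=(1, q))
        params = LCLParameters(beta=beta, lam=lam)
        ll, grad, _, _ = _ll_grad(params, gd, uptr)
        theta = params.pack()
        h = 1e-6
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            lp = lcl_loglik(LCLParameters.unpack(tp, 2, gd.p, q), gd)
            lm = lcl_loglik(LCLParameters.unpack(tm, 2, gd.p, q), gd)
            assert grad[j] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-5)


class TestInformationCriteria:
    def test_aic(self):
        assert information_criteria(-100.0, 5, 100).aic == pytest.approx(210.0)

    def test_bic(self):
        ics = information_criteria(-100.0, 5, 100)
        assert ics.bic == pytest.approx(210.0 + 5 * (np.log(100) - 2), abs=1e-10)
        assert ics.bic == pytest.approx(223.0259, abs=1e-3)

    def test_caic_minus_bic_is_k(self):
        for k in (1, 7, 30):
            ics = information_criteria(-57.0, k, 314)
            assert ics.caic - ics.bic == pytest.approx(k)


class TestFitLCL:
    def test_s1_reproduces_mnl(self):
        gd = lcl_sim(8, n_resp=40, n_plots=44)
        fit1 = fit_lcl(gd, S=1)
        base = fit_mnl(gd)
        np.testing.assert_allclose(fit1.params.beta[0], base.params, atol=1e-6)
        assert fit1.loglik == pytest.approx(base.loglik, abs=1e-8)

    def test_determinism(self):
        gd = lcl_sim(9, n_resp=60, n_plots=66)
        f1 = fit_lcl(gd, S=2, seed=3, n_starts=2)
        f2 = fit_lcl(gd, S=2, seed=3, n_starts=2)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.params.beta, f2.params.beta)

    def test_em_history_monotone(self):
        gd = lcl_sim(10, n_resp=80, n_plots=88)
        fit = fit_lcl(gd, S=2, seed=0, n_starts=2)
        hist = np.asarray(fit.em_history)
        assert np.all(np.diff(hist) >= -1e-6 * (1 + np.abs(hist[:-1])))

    def test_posterior_consistency(self):
        gd = lcl_sim(11, n_resp=100, n_plots=110)
        fit = fit_lcl(gd, S=2, seed=1, n_starts=3)
        np.testing.assert_allclose(
            fit.posterior.mean(axis=0), fit.class_shares, atol=1e-6
        )
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_classes_ordered_by_share(self):
        gd = lcl_sim(12, n_resp=80, n_plots=88, shares=(0.7, 0.3))
        fit = fit_lcl(gd, S=2, seed=1, n_starts=3)
        assert fit.class_shares[0] >= fit.class_shares[1]

    def test_permutation_invariance_of_loglik(self):
        gd = lcl_sim(13, n_resp=30, n_plots=33)
        rng = np.random.default_rng(3)
        q = gd.Z.shape[1]
        beta = rng.normal(scale=0.5, size=(3, gd.p))
        lam = rng.normal(scale=0.5, size=(2, q))
        ll = lcl_loglik(LCLParameters(beta=beta, lam=lam), gd)
        # permute classes (0,1,2) -> (2,0,1); rebuild lam against new reference
        order = np.array([2, 0, 1])
        lam_full = np.vstack([lam, np.zeros(q)])[order]
        lam_perm = lam_full[:2] - lam_full[2]
        ll_perm = lcl_loglik(
            LCLParameters(beta=beta[order], lam=lam_perm), gd
        )
        assert ll_perm == pytest.approx(ll, abs=1e-10)

    def test_two_class_recovery(self):
        truth_shares = (0.6, 0.4)
        gd = lcl_sim(14, n_resp=950, n_plots=1000, shares=truth_shares)
        fit = fit_lcl(gd, S=2, seed=2, n_starts=4, compute_cov=True)
        np.testing.assert_allclose(
            fit.class_shares, truth_shares, atol=0.05
        )
        beta_truth = np.array(
            [
                [-0.2, -0.3, 1.5, 0.8, 1.2, 0.5, 0.4, 0.0, 0.0],
                [-2.5, 0.1, -1.0, -0.6, 0.2, -1.5, -0.8, 0.0, 0.0],
            ]
        )
        se = np.sqrt(np.clip(np.diag(fit.cov), 1e-12, None))[: 2 * gd.p]
        se = se.reshape(2, gd.p)
        within = np.abs(fit.params.beta - beta_truth) < 3 * se + 0.05
        assert within.mean() > 0.9


class TestSelectClasses:
    def test_table_has_all_rows(self):
        gd = lcl_sim(15, n_resp=60, n_plots=66)
        res = select_classes(gd, [1, 2], n_starts=2, seed=0)
        assert len(res.table) == 2

    def test_one_class_data_selects_lower_bound(self):
        beta = np.tile(
            np.array([[-0.5, -0.2, 1.0, 0.5, 0.8, 0.3, 0.2, 0.0, 0.0]]), (1, 1)
        )
        spec = ClassSpec(beta=beta, shares=(1.0,), membership_covariates=("gender",))
        cfg = SimulationConfig(n_respondents=250, n_plots=260,
                               class_spec=spec, rng_seed=16)
        ds = ac.simulate_choices_lcl(cfg)
        gd = grouped_design(ds, membership_covariates=("gender",))
        res = select_classes(gd, [1, 2], criterion="bic", n_starts=2, seed=1)
        assert res.chosen_S == 1


class TestWald:
    def test_statistic_nonnegative_and_df(self):
        gd = lcl_sim(17, n_resp=120, n_plots=132)
        fit = fit_lcl(gd, S=2, seed=0, n_starts=2, compute_cov=True)
        res = wald_joint_test(fit)
        q = gd.Z.shape[1]
        assert res.statistic >= 0
        assert res.df == gd.p + q  # (S-1) * (p + q) with S = 2
        assert 0.0 <= res.pvalue <= 1.0

    def test_membership_covariates_df(self):
        gd = lcl_sim(18, n_resp=120, n_plots=132)
        fit = fit_lcl(gd, S=2, seed=0, n_starts=2, compute_cov=True)
        res = wald_joint_test(fit, restrictions="membership_covariates")
        assert res.df == gd.Z.shape[1] - 1

    def test_needs_two_classes(self):
        gd = lcl_sim(19, n_resp=30, n_plots=33)
        fit = fit_lcl(gd, S=1)
        with pytest.raises(ValueError, match="S >= 2"):
            wald_joint_test(fit)
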
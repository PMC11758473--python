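"""APIM estimation: design building, FIML, sandwich SEs, multigroup."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from conftest import cohort_frames, make_regression_design
from emodyad.apim import (XNAMES, ApimSpec, FitError, build_design, fit_apim,
                          fit_multigroup, robust_se, standardize)
from emodyad.apim import _case_scores, _neg_ll_and_grad, _theta_of, _to_natural
from emodyad.synthetic import SyntheticConfig, generate_dyads

BETA1 = np.array([0.5, 0.5, 0.1, 0.1, 0.0, 0.0, 0.0])
BETA2 = np.array([0.2, 0.0, 0.0, 0.0, 0.55, 0.1, 0.1])
RESID = np.array([[0.2, 0.06], [0.06, 0.15]])


class TestBuildDesign:
    def _frames(self, n=12, seed=0):
        dyads, _ = generate_dyads(SyntheticConfig(n_dyads=n, seed=seed,
                                                  baseline_missing_rate=0.0))
        return cohort_frames(dyads)

    def test_shape_and_centering(self):
        summaries, base = self._frames()
        design = build_design(summaries, base, ApimSpec("negative", "anxious"))
        assert design.X.shape == (12, 7) and design.Y.shape == (12, 2)
        for name in ("a_mean", "a_div", "c_mean", "c_div"):
            assert abs(design.xcol(name).mean()) < 1e-12

    def test_product_of_centered_factors(self):
        summaries, base = self._frames(seed=1)
        design = build_design(summaries, base, ApimSpec("positive", "depressive"))
        np.testing.assert_allclose(
            design.xcol("a_mean_x_div"),
            design.xcol("a_mean") * design.xcol("a_div"), atol=1e-14)

    def test_no_centering_option(self):
        summaries, base = self._frames(seed=2)
        design = build_design(summaries, base, ApimSpec(), center=False)
        assert design.centers == {k: 0.0 for k in design.centers}
        assert design.xcol("a_mean").mean() > 0.1

    def test_zero_dyads_is_error(self):
        summaries, base = self._frames(seed=3)
        base = base.assign(anxious_mean=np.nan)
        with pytest.raises(FitError):
            build_design(summaries, base, ApimSpec("negative", "anxious"))


class TestFitComplete:
    def test_exact_fit_recovers_identity(self):
        rng = np.random.default_rng(0)
        design, _ = make_regression_design(rng, 50, BETA1, BETA2, RESID)
        design.Y[:, 0] = design.xcol("a_mean")  # outcome == predictor, no noise
        fit = fit_apim(design)
        assert fit.coef("y_adol", "a_mean") == pytest.approx(1.0, abs=1e-10)
        for name in XNAMES:
            if name != "a_mean":
                assert fit.coef("y_adol", name) == pytest.approx(0.0, abs=1e-10)
        assert fit.Sigma[0, 0] == pytest.approx(0.0, abs=1e-16)

    def test_equals_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        design, _ = make_regression_design(rng, 200, BETA1, BETA2, RESID)
        fit = fit_apim(design)
        for k in range(2):
            ols, *_ = np.linalg.lstsq(design.X, design.Y[:, k], rcond=None)
            np.testing.assert_allclose(fit.B[:, k], ols, atol=1e-10)
        E = design.Y - design.X @ fit.B
        np.testing.assert_allclose(fit.Sigma, E.T @ E / 200, atol=1e-10)
        n = 200
        ll_closed = -n * np.log(2 * np.pi) - n / 2 * np.log(np.linalg.det(fit.Sigma)) - n
        assert fit.loglik == pytest.approx(ll_closed, abs=1e-8)

    def test_scores_sum_to_zero_at_optimum(self):
        rng = np.random.default_rng(2)
        design, _ = make_regression_design(rng, 150, BETA1, BETA2, RESID)
        fit = fit_apim(design)
        _, scores = _case_scores(_theta_of(fit), design.X, design.Y)
        assert np.linalg.norm(scores.sum(axis=0)) < 1e-6

    def test_iterative_path_matches_closed_form(self):
        """The quasi-Newton FIML route, run on complete data, lands on the
        same maximum as the closed form."""
        rng = np.random.default_rng(3)
        design, _ = make_regression_design(rng, 120, BETA1, BETA2, RESID)
        fit = fit_apim(design)
        p = design.X.shape[1]
        phi0 = np.concatenate([fit.B[:, 0] + 0.2, fit.B[:, 1] - 0.2,
                               [0.0, 0.0, 0.0]])
        res = optimize.minimize(_neg_ll_and_grad, phi0,
                                args=(design.X, design.Y), jac=True,
                                method="BFGS", options={"gtol": 1e-10})
        theta = _to_natural(res.x, p)
        np.testing.assert_allclose(theta[:p], fit.B[:, 0], atol=1e-6)
        np.testing.assert_allclose(theta[p:2 * p], fit.B[:, 1], atol=1e-6)
        assert theta[2 * p + 2] == pytest.approx(fit.Sigma[0, 1], abs=1e-6)

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(4)
        design, _ = make_regression_design(rng, 60, BETA1, BETA2, RESID)
        design.X[:, 2] = 2.0 * design.X[:, 1]
        with pytest.raises(FitError, match="collinear"):
            fit_apim(design)


class TestFiml:
    def test_fiml_recovers_truth_under_mcar(self):
        rng = np.random.default_rng(5)
        design, B = make_regression_design(rng, 3000, BETA1, BETA2, RESID,
                                           miss_rate=0.3)
        fit = fit_apim(design)
        assert fit.converged
        np.testing.assert_allclose(fit.B, B, atol=0.06)
        assert fit.Sigma[0, 1] == pytest.approx(RESID[0, 1], abs=0.02)

    def test_fiml_loglik_sums_marginals(self):
        rng = np.random.default_rng(6)
        design, _ = make_regression_design(rng, 80, BETA1, BETA2, RESID,
                                           miss_rate=0.25)
        fit = fit_apim(design)
        theta = _theta_of(fit)
        ll, _ = _case_scores(theta, design.X, design.Y)
        # independent recomputation: bivariate density for complete rows,
        # univariate marginal for partially observed rows
        from scipy import stats

        total = 0.0
        for i in range(design.n):
            x, y = design.X[i], design.Y[i]
            mu = x @ fit.B
            obs = ~np.isnan(y)
            if obs.all():
                total += stats.multivariate_normal.logpdf(y, mu, fit.Sigma)
            else:
                k = int(np.flatnonzero(obs)[0])
                total += stats.norm.logpdf(y[k], mu[k], np.sqrt(fit.Sigma[k, k]))
        assert ll == pytest.approx(total, abs=1e-8)
        assert fit.loglik == pytest.approx(total, abs=1e-8)


class TestRobustSE:
    def test_matches_classical_when_homoskedastic(self):
        rng = np.random.default_rng(7)
        design, _ = make_regression_design(rng, 2000, BETA1, BETA2, RESID)
        fit = robust_se(fit_apim(design), design)
        for out in ("y_adol", "y_cg"):
            for name in XNAMES[1:]:
                i = fit.param_index(out, name)
                ratio = np.sqrt(fit.cov_robust[i, i] / fit.cov_classical[i, i])
                assert 0.95 <= ratio <= 1.05

    def test_heteroskedastic_coverage(self):
        """Sandwich CIs hold ~95% coverage under error SD proportional to
        |x|; classical CIs undercover."""
        rng = np.random.default_rng(8)
        hits_rob, hits_cls = [], []
        for _ in range(500):
            design, B = make_regression_design(rng, 300, BETA1, BETA2, RESID,
                                               hetero=True)
            fit = robust_se(fit_apim(design), design)
            i = fit.param_index("y_adol", "a_mean")
            b, true = fit.B[1, 0], B[1, 0]
            se_r = np.sqrt(fit.cov_robust[i, i])
            se_c = np.sqrt(fit.cov_classical[i, i])
            hits_rob.append(abs(b - true) <= 1.96 * se_r)
            hits_cls.append(abs(b - true) <= 1.96 * se_c)
        cov_rob, cov_cls = np.mean(hits_rob), np.mean(hits_cls)
        assert 0.93 <= cov_rob <= 0.97
        assert cov_cls < cov_rob
        assert cov_cls < 0.93


class TestStandardize:
    def _fit(self, seed=9, n=300):
        rng = np.random.default_rng(seed)
        design, _ = make_regression_design(rng, n, BETA1, BETA2, RESID)
        return design, standardize(robust_se(fit_apim(design), design), design)

    def test_zero_coefficient_is_zero_beta(self):
        design, fit = self._fit()
        tab = fit.summary_table().set_index(["outcome", "path"])
        b = fit.coef("y_adol", "c_div")
        assert tab.loc[("y_adol", "c_div"), "beta"] == pytest.approx(
            b * fit.sd_x["c_div"] / fit.sd_y["y_adol"])

    def test_rescaling_invariance(self):
        design, fit = self._fit(seed=10)
        scaled = design.subset(np.ones(design.n, dtype=bool))
        scaled.X = design.X.copy()
        scaled.X[:, 1] *= 10.0
        fit2 = standardize(robust_se(fit_apim(scaled), scaled), scaled)
        t1 = fit.summary_table().set_index(["outcome", "path"])
        t2 = fit2.summary_table().set_index(["outcome", "path"])
        for key in (("y_adol", "a_mean"), ("y_cg", "a_mean")):
            assert t1.loc[key, "beta"] == pytest.approx(t2.loc[key, "beta"], abs=1e-12)
            assert t1.loc[key, "se_beta"] == pytest.approx(t2.loc[key, "se_beta"],
                                                           rel=1e-9)

    def test_beta_equals_zscored_refit(self):
        design, fit = self._fit(seed=11)
        Z = design.X.copy()
        sds = design.X[:, 1:].std(axis=0, ddof=1)
        Z[:, 1:] = design.X[:, 1:] / sds
        y = design.Y[:, 0] / design.Y[:, 0].std(ddof=1)
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        tab = fit.summary_table().set_index(["outcome", "path"])
        for j, name in enumerate(XNAMES[1:], start=1):
            assert tab.loc[("y_adol", name), "beta"] == pytest.approx(coef[j], abs=1e-10)

    def test_ci_is_beta_pm_1_96_se(self):
        _, fit = self._fit(seed=12)
        tab = fit.summary_table(level=0.95)
        np.testing.assert_allclose(tab["ci_low"],
                                   tab["beta"] - 1.959963984540054 * tab["se_beta"])


class TestMultigroup:
    def test_identical_groups_identical_fits(self):
        rng = np.random.default_rng(13)
        design, _ = make_regression_design(rng, 80, BETA1, BETA2, RESID)
        double = design.subset(np.ones(80, dtype=bool))
        double.X = np.vstack([design.X, design.X])
        double.Y = np.vstack([design.Y, design.Y])
        double.dyad_ids = design.dyad_ids + [f"{d}b" for d in design.dyad_ids]
        groups = np.array(["g1"] * 80 + ["g2"] * 80)
        grouped = fit_multigroup(double, groups)
        np.testing.assert_allclose(grouped.fits["g1"].B, grouped.fits["g2"].B,
                                   atol=1e-10)

    def test_undersized_group_excluded(self):
        rng = np.random.default_rng(14)
        design, _ = make_regression_design(rng, 104, BETA1, BETA2, RESID)
        groups = np.array(["big"] * 100 + ["tiny"] * 4)
        grouped = fit_multigroup(design, groups, min_group_n=10)
        assert grouped.excluded_groups == {"tiny": 4}
        assert set(grouped.fits) == {"big"}

    def test_groupwise_effects_recovered(self):
        rng = np.random.default_rng(15)
        b_boy, b_girl = BETA1.copy(), BETA1.copy()
        b_boy[1], b_girl[1] = 0.2, 0.6
        d1, _ = make_regression_design(rng, 1000, b_boy, BETA2, RESID)
        d2, _ = make_regression_design(rng, 1000, b_girl, BETA2, RESID)
        merged = d1.subset(np.ones(1000, dtype=bool))
        merged.X = np.vstack([d1.X, d2.X])
        merged.Y = np.vstack([d1.Y, d2.Y])
        merged.dyad_ids = d1.dyad_ids + [f"{d}g" for d in d2.dyad_ids]
        groups = np.array(["boy"] * 1000 + ["girl"] * 1000)
        grouped = fit_multigroup(merged, groups)
        assert grouped.fits["boy"].coef("y_adol", "a_mean") == pytest.approx(0.2, abs=0.06)
        assert grouped.fits["girl"].coef("y_adol", "a_mean") == pytest.approx(0.6, abs=0.06)

    def test_all_groups_undersized_is_error(self):
        rng = np.random.default_rng(16)
        design, _ = make_regression_design(rng, 8, BETA1, BETA2, RESID)
        with pytest.raises(FitError):
            fit_multigroup(design, np.array(["a"] * 4 + ["b"] * 4), min_group_n=10)
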
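"""Weibull AFT likelihood, fitting, summary inference and family comparison."""

import numpy as np
import pytest
from scipy import stats

from donorcalc.aft import (AFTParameters, DomainError, FittedAFT,
                           NoCovarianceError, RankDeficientError,
                           coefficient_table, compare_distributions,
                           fit_weibull_aft, log_likelihood, shape_row,
                           term_level_tests)
from donorcalc.design import DesignMatrix, default_spec
from donorcalc.reference import (reference_model, reference_standard_errors,
                                 reference_summary, summary_from_estimates)
from tests.conftest import toy_design


def single_obs_design(t, event):
    return DesignMatrix(["Intercept"], np.ones((1, 1)), np.array([float(t)]),
                        np.array([event]))


class TestLogLikelihood:
    def test_exponential_event_closed_form(self):
        # k=1, mu=0: density e^{-t}, so log f(1) = -1
        p = AFTParameters(beta={"Intercept": 0.0}, shape_k=1.0)
        assert log_likelihood(p, single_obs_design(1.0, True)) == pytest.approx(-1.0)

    def test_exponential_censored_closed_form(self):
        # k=1, mu=0: survival e^{-t}, so log S(2) = -2
        p = AFTParameters(beta={"Intercept": 0.0}, shape_k=1.0)
        assert log_likelihood(p, single_obs_design(2.0, False)) == pytest.approx(-2.0)

    def test_matches_term_by_term_scipy_transcription(self):
        """Independent oracle: sum scipy weibull_min log-density for events
        and log-survival for censored records, term by term."""
        d = toy_design(seed=5, n=20, p=3)
        rng = np.random.default_rng(1)
        beta = {c: v for c, v in zip(d.column_names, rng.normal(5, 1, 3))}
        k = 1.7
        p = AFTParameters(beta=beta, shape_k=k)
        expected = 0.0
        bvec = np.array([beta[c] for c in d.column_names])
        for i in range(d.n):
            scale = np.exp(d.X[i] @ bvec)
            if d.events[i]:
                expected += stats.weibull_min.logpdf(d.times[i], k, scale=scale)
            else:
                expected += stats.weibull_min.logsf(d.times[i], k, scale=scale)
        assert log_likelihood(p, d) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_time_rejected(self):
        p = AFTParameters(beta={"Intercept": 0.0}, shape_k=1.0)
        with pytest.raises(DomainError):
            log_likelihood(p, single_obs_design(0.0, True))

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(DomainError):
            AFTParameters(beta={"Intercept": 0.0}, shape_k=0.0)


class TestFit:
    def test_parameter_recovery_within_3_joint_se(self):
        rng = np.random.default_rng(42)
        n, k_true = 2000, 1.5
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, .4, n)])
        beta_true = np.array([6.5, 0.4, -0.3])
        t = np.exp(X @ beta_true) * (-np.log(rng.uniform(size=n))) ** (1 / k_true)
        c = rng.uniform(0, np.quantile(t, 0.9), size=n)
        times, events = np.minimum(t, c), t <= c
        assert 0.3 < 1 - events.mean() < 0.6  # ~40% censoring
        d = DesignMatrix(["Intercept", "x1", "x2"], X, times, events)
        fit = fit_weibull_aft(d)
        assert fit.converged
        est = np.append(fit.params.beta_vector(), np.log(fit.params.shape_k))
        truth = np.append(beta_true, np.log(k_true))
        se = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(est - truth) < 3 * se)

    def test_intercept_only_matches_grid_search_oracle(self):
        """2-parameter grid search over (mu, k) maximizing the uncensored
        Weibull likelihood agrees with the analytic fit."""
        rng = np.random.default_rng(3)
        times = stats.weibull_min.rvs(1.8, scale=900, size=300, random_state=rng)
        d = DesignMatrix(["Intercept"], np.ones((300, 1)), times,
                         np.ones(300, dtype=bool))
        fit = fit_weibull_aft(d)
        mus = np.linspace(6.5, 7.2, 141)
        ks = np.linspace(1.2, 2.4, 121)
        ll = np.array([[stats.weibull_min.logpdf(times, k, scale=np.exp(m)).sum()
                        for k in ks] for m in mus])
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        assert fit.params.beta["Intercept"] == pytest.approx(mus[i], abs=0.01)
        assert fit.params.shape_k == pytest.approx(ks[j], abs=0.02)
        # the MLE dominates every grid point
        assert fit.loglik >= ll.max() - 1e-9

    def test_reorder_invariance(self):
        d = toy_design(seed=11, n=120, p=3)
        fit1 = fit_weibull_aft(d)
        perm = np.random.default_rng(0).permutation(d.n)
        d2 = DesignMatrix(d.column_names, d.X[perm], d.times[perm], d.events[perm])
        fit2 = fit_weibull_aft(d2)
        assert np.allclose(fit1.params.beta_vector(), fit2.params.beta_vector(),
                           atol=1e-8)
        assert fit1.params.shape_k == pytest.approx(fit2.params.shape_k, abs=1e-8)

    def test_matches_lifelines(self, fitted737, cohort737, ref_spec):
        """Independent oracle: lifelines' Weibull AFT on the same design."""
        import pandas as pd
        from lifelines import WeibullAFTFitter
        from donorcalc import build_design_matrix
        d = build_design_matrix(cohort737, ref_spec)
        df = pd.DataFrame(d.X[:, 1:], columns=d.column_names[1:])
        df["T"] = np.maximum(d.times, 0.5)
        df["E"] = d.events
        ll = WeibullAFTFitter().fit(df, "T", "E")
        lam = ll.params_["lambda_"]
        for c in d.column_names[1:]:
            assert fitted737.params.beta[c] == pytest.approx(lam[c], abs=2e-4)
        assert fitted737.params.beta["Intercept"] == pytest.approx(
            lam["Intercept"], abs=2e-4)
        assert fitted737.params.shape_k == pytest.approx(
            float(np.exp(ll.params_["rho_"]["Intercept"])), abs=2e-4)

    def test_rank_deficient_design_names_columns(self):
        d = toy_design(seed=2, n=50, p=2)
        X = np.column_stack([d.X, d.X[:, 1]])
        dd = DesignMatrix(d.column_names + ["x1_copy"], X, d.times, d.events)
        with pytest.raises(RankDeficientError):
            fit_weibull_aft(dd)

    def test_requires_an_event(self):
        d = toy_design(seed=4, n=10)
        dd = DesignMatrix(d.column_names, d.X, d.times,
                          np.zeros(d.n, dtype=bool))
        with pytest.raises(ValueError, match="event"):
            fit_weibull_aft(dd)

    def test_zero_times_shifted_with_warning(self):
        d = toy_design(seed=9, n=60)
        d.times[0] = 0.0
        with pytest.warns(UserWarning, match="shifted"):
            fit = fit_weibull_aft(d)
        assert fit.converged


class TestCoefficientTable:
    def test_wald_identities_exact(self, fitted737):
        tab = coefficient_table(fitted737)
        for row in tab.rows[:-1]:
            assert row.z == pytest.approx(row.coef / row.se, rel=1e-12)
            assert row.p == pytest.approx(2 * stats.norm.sf(abs(row.z)), rel=1e-12)
            assert row.ci_high - row.coef == pytest.approx(
                row.coef - row.ci_low, rel=1e-9)
            assert row.ci_high == pytest.approx(
                row.coef + stats.norm.ppf(0.975) * row.se, rel=1e-12)

    def test_published_z_values(self):
        """The printed inference columns are recoverable from coefficient
        and standard error alone."""
        model = reference_model()
        ses, shape_se = reference_standard_errors()
        tab = summary_from_estimates(model.params.beta, ses,
                                     model.params.shape_k, shape_se)
        rows = {r.term: r for r in tab.rows}
        assert round(rows["AgePatient"].z, 2) == 2.15
        assert round(rows["Intercept"].z, 2) == 30.77
        assert round(rows["HLA_2:AgePatient"].z, 2) == -2.93
        assert rows["AgePatient"].ci_high == pytest.approx(0.0314226, abs=5e-8)

    def test_shape_ci_is_log_scale_and_asymmetric(self):
        row = shape_row(1.69843, 0.0654468)
        assert row.ci_low == pytest.approx(1.57488, abs=5e-6)
        assert row.ci_high == pytest.approx(1.83167, abs=5e-6)
        # asymmetric about the estimate
        assert (row.ci_high - row.coef) != pytest.approx(row.coef - row.ci_low)

    def test_zero_coefficient_row(self):
        tab = summary_from_estimates({"a": 0.0}, {"a": 0.5})
        r = tab.rows[0]
        assert r.z == 0.0 and r.p == 1.0
        assert r.ci_low == -r.ci_high

    def test_fixture_without_covariance_refuses_table(self, ref_model):
        with pytest.raises(NoCovarianceError):
            coefficient_table(ref_model)

    def test_text_and_csv_exports(self, fitted737, tmp_path):
        tab = coefficient_table(fitted737)
        text = tab.to_text()
        assert text.count("\n") == len(tab.rows)  # header + one line per row
        assert "Shape" in text
        tab.to_csv(tmp_path / "t.csv")
        import pandas as pd
        back = pd.read_csv(tmp_path / "t.csv")
        assert len(back) == len(tab.rows)


class TestTermLevelTests:
    def test_single_coefficient_term_equals_z_squared(self, fitted737, ref_spec):
        tab = {r.term: r for r in coefficient_table(fitted737).rows}
        tests = dict((t, (chi2, df, p)) for t, chi2, df, p
                     in term_level_tests(fitted737, ref_spec))
        chi2, df, p = tests["AgePatient"]
        z = tab["AgePatient"].z
        assert df == 1
        assert chi2 == pytest.approx(z * z, rel=1e-9)
        assert p == pytest.approx(tab["AgePatient"].p, rel=1e-9)

    def test_two_df_term_matches_matrix_arithmetic(self, fitted737, ref_spec):
        cols = fitted737.params.column_names
        ii = [cols.index("HLA_2"), cols.index("HLA_3")]
        b = fitted737.params.beta_vector(["HLA_2", "HLA_3"])
        V = fitted737.covariance[np.ix_(ii, ii)]
        expected = float(b @ np.linalg.inv(V) @ b)
        tests = {t: (chi2, df) for t, chi2, df, _ in
                 term_level_tests(fitted737, ref_spec)}
        assert tests["HLA"][1] == 2
        assert tests["HLA"][0] == pytest.approx(expected, rel=1e-9)

    def test_zero_coefficients_give_p_one(self):
        fit = FittedAFT(
            params=AFTParameters(beta={"Intercept": 5.0, "a_2": 0.0, "a_3": 0.0},
                                 shape_k=1.0),
            covariance=np.eye(4), loglik=0.0, n=10, n_events=5)
        from donorcalc.design import Factor, ModelSpec
        spec = ModelSpec(factors=(Factor("a", ("1", "2", "3"), "1"),),
                         continuous=(), interactions=())
        (term, chi2, df, p), = [t for t in term_level_tests(fit, spec)]
        assert chi2 == 0.0 and p == 1.0 and df == 2


class TestCompareDistributions:
    def test_single_family_request(self):
        d = toy_design(seed=6, n=150)
        res = compare_distributions(d, families=("weibull",))
        assert len(res) == 1 and res[0].family == "weibull"

    def test_exponential_data_gives_shape_near_one(self):
        rng = np.random.default_rng(8)
        n = 1200
        t = rng.exponential(800, size=n)
        c = rng.uniform(0, 2400, size=n)
        d = DesignMatrix(["Intercept"], np.ones((n, 1)),
                         np.minimum(t, c), t <= c)
        res = {f.family: f for f in compare_distributions(d)}
        assert res["weibull"].shape_k == pytest.approx(1.0, abs=0.08)
        # nested model: AD statistics agree within noise
        assert res["weibull"].ad_statistic == pytest.approx(
            res["exponential"].ad_statistic, rel=0.2)

    def test_exponential_limit_reproduces_rate_mle(self):
        """With k fixed at 1 (exponential family), intercept-only and no
        censoring, the MLE is the closed-form rate: exp(-mu) = events/total
        time."""
        rng = np.random.default_rng(12)
        t = rng.exponential(500, size=400)
        d = DesignMatrix(["Intercept"], np.ones((400, 1)), t,
                         np.ones(400, dtype=bool))
        from donorcalc.aft import _family_nll
        import scipy.optimize
        nll = _family_nll("exponential")
        r = scipy.optimize.minimize(
            lambda th: nll(th, d.X, np.log(d.times), d.events.astype(float),
                           fixed_k=1.0), np.array([6.0]), method="BFGS")
        assert r.x[0] == pytest.approx(np.log(t.sum() / len(t)), abs=1e-5)
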
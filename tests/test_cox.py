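import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

import epvsim as e
from epvsim.cohort import Cohort
from epvsim.cox import CoxFit


def breslow_loglik_oracle(beta, x, time, event):
    """Independent Breslow partial log-likelihood (plain suffix sums)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    eta = x @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")
    ev = event == 1
    return float(np.sum(eta[ev] - np.log(s0[first][ev])))


class TestFitAgainstOracles:
    def test_grid_search_oracle_on_fixture(self, five_subject_cohort):
        """Newton estimate equals the argmax of a dense grid search.

        The grid oracle on beta in [-10, 10] step 1e-4 gives beta = -0.8341
        (loglik -3.4433216381), computed once from the same Breslow
        likelihood written independently above.
        """
        coh = five_subject_cohort
        fit = e.fit_cox(coh, ["x"])
        assert fit.converged
        grid = np.arange(-10.0, 10.0, 1e-4)
        lls = np.array(
            [breslow_loglik_oracle([b], coh.covariates, coh.time, coh.event) for b in grid]
        )
        assert fit.coefficients[0] == pytest.approx(grid[lls.argmax()], abs=1e-3)
        assert fit.coefficients[0] == pytest.approx(-0.8341, abs=1e-3)
        assert fit.loglik == pytest.approx(-3.4433216381, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_covariate_optimizer_oracle_small_n(self, seed):
        """For p = 2, n <= 20, the fit matches an independent numerical argmax."""
        rng = np.random.default_rng(seed)
        n = 16
        x = np.column_stack([rng.standard_normal(n), (rng.random(n) < 0.5).astype(float)])
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.7).astype(int)
        coh = Cohort(x, time, event, ["a", "b"])
        fit = e.fit_cox(coh, ["a", "b"])
        if not fit.converged:
            pytest.skip("tiny sample hit monotone likelihood")
        res = minimize(
            lambda b: -breslow_loglik_oracle(b, x, time, event),
            np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-3)

    def test_matches_statsmodels_breslow_with_ties(self, rng):
        """Coefficients, SEs and loglik agree with statsmodels PHReg on tied data."""
        PHReg = pytest.importorskip("statsmodels.duration.hazard_regression").PHReg
        n = 400
        x = np.column_stack([rng.standard_normal(n), (rng.random(n) < 0.3).astype(float)])
        t = rng.exponential(1, n) / np.exp(0.5 * x[:, 0] + 0.8 * x[:, 1])
        c = rng.uniform(0, 2, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        idx = rng.integers(0, n, n)  # resample with replacement: creates ties
        coh = Cohort(x[idx], time[idx], event[idx], ["a", "b"])
        fit = e.fit_cox(coh, ["a", "b"])
        m = PHReg(coh.time, coh.covariates, status=coh.event, ties="breslow").fit()
        np.testing.assert_allclose(fit.coefficients, m.params, rtol=1e-6)
        np.testing.assert_allclose(fit.std_errors, m.bse, rtol=1e-5)
        assert fit.loglik == pytest.approx(float(m.model.loglike(m.params)), rel=1e-9)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        n = 300
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1, n) / np.exp(0.4 * x[:, 0] - 0.3 * x[:, 1])
        c = rng.uniform(0, 3, n)
        coh = Cohort(x, np.minimum(t, c), (t <= c).astype(int), ["a", "b"])
        fit = e.fit_cox(coh, ["a", "b"])
        df = pd.DataFrame({"T": coh.time, "E": coh.event, "a": x[:, 0], "b": x[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(fit.coefficients, cph.params_[["a", "b"]], atol=1e-4)

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 200
        x = rng.standard_normal((n, 1))
        t = rng.exponential(1, n) / np.exp(0.5 * x[:, 0])
        coh = Cohort(x, t, np.ones(n, dtype=int), ["a"])
        fb = e.fit_cox(coh, ["a"], e.FitConfig(ties="breslow"))
        fe = e.fit_cox(coh, ["a"], e.FitConfig(ties="efron"))
        np.testing.assert_allclose(fb.coefficients, fe.coefficients, atol=1e-8)


class TestConvergenceRule:
    def test_symmetric_groups_give_zero_coefficient(self):
        # identical event/censoring pattern in both covariate groups
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
        fit = e.fit_cox(Cohort(x, time, event, ["x"]), ["x"])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_monotone_likelihood_detected(self):
        # every event has x = 1 while x = 0 subjects remain at risk
        x = np.array([[1.0], [1.0], [0.0], [0.0], [0.0]])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 0, 0])
        fit = e.fit_cox(Cohort(x, time, event, ["x"]), ["x"])
        assert fit.monotone_flag
        assert not fit.converged
        assert np.all(np.isnan(fit.std_errors))

    def test_zero_events_rejected(self):
        coh = Cohort(np.zeros((3, 1)), np.ones(3), np.zeros(3, dtype=int), ["x"])
        with pytest.raises(ValueError, match="no events"):
            e.fit_cox(coh, ["x"])

    def test_missing_variable_rejected(self, five_subject_cohort):
        with pytest.raises(KeyError):
            e.fit_cox(five_subject_cohort, ["y"])

    def test_score_zero_and_loglik_above_null_at_optimum(self, rng):
        from epvsim.cox import _PartialLikelihood

        for _ in range(5):
            n = 80
            x = rng.standard_normal((n, 3))
            t = rng.exponential(1, n) / np.exp(x @ np.array([0.3, -0.2, 0.5]))
            c = rng.uniform(0, 2, n)
            coh = Cohort(x, np.minimum(t, c), (t <= c).astype(int), ["a", "b", "c"])
            fit = e.fit_cox(coh, ["a", "b", "c"])
            assert fit.converged
            pl = _PartialLikelihood(coh.covariates, coh.time, coh.event, "breslow")
            _, score, _ = pl.score_info(fit.coefficients)
            assert np.max(np.abs(score)) < 1e-6
            assert fit.loglik >= fit.loglik_null


class TestWaldInference:
    def _fixture_fit(self):
        return CoxFit(
            names=["a"],
            coefficients=np.array([1.0]),
            std_errors=np.array([0.5]),
            loglik=-1.0,
            loglik_null=-2.0,
            converged=True,
            monotone_flag=False,
            n_iter=3,
            n_events=4,
        )

    def test_pvalue_limits(self):
        fit = self._fixture_fit()
        fit.coefficients = np.array([0.0])
        assert e.wald_pvalues(fit)[0] == pytest.approx(1.0)
        fit.coefficients = np.array([1.96 * 0.5])
        assert e.wald_pvalues(fit)[0] == pytest.approx(0.05, abs=1e-3)

    def test_pvalue_matches_normal_oracle_on_fixture(self, five_subject_cohort):
        fit = e.fit_cox(five_subject_cohort, ["x"])
        z = fit.coefficients[0] / fit.std_errors[0]
        expected = 2 * stats.norm.sf(abs(z))
        assert e.wald_pvalues(fit)[0] == pytest.approx(expected, rel=1e-12)

    def test_confint_arithmetic_and_containment(self):
        fit = self._fixture_fit()
        ci = e.confint95(fit)
        assert ci[0, 0] == pytest.approx(1 - 1.959964 * 0.5)
        assert ci[0, 1] == pytest.approx(1 + 1.959964 * 0.5)
        assert ci[0, 0] < fit.coefficients[0] < ci[0, 1]

    def test_nonconverged_fit_rejected(self):
        fit = self._fixture_fit()
        fit.converged = False
        with pytest.raises(ValueError):
            e.wald_pvalues(fit)
        with pytest.raises(ValueError):
            e.confint95(fit)

    def test_ci_width_scales_inverse_sqrt_events(self, dev_cohort):
        """Mean interval width shrinks like 1/sqrt(k) across EPV settings."""
        widths = {}
        for epv, seed in ((10, 50), (40, 51)):
            ne, nn = e.replicate_counts(epv, 3)
            rng = np.random.default_rng(seed)
            w = []
            for _ in range(30):
                fit = e.fit_cox(e.epv_sample(dev_cohort, ne, nn, rng), e.model_variables(3))
                if fit.converged:
                    w.append(np.mean(e.confint95(fit)[:, 1] - e.confint95(fit)[:, 0]))
            widths[epv] = np.mean(w)
        assert widths[40] / widths[10] == pytest.approx(np.sqrt(10 / 40), rel=0.25)


class TestPrognosticIndex:
    def test_linear_predictor(self, five_subject_cohort):
        fit = CoxFit(
            names=["x"], coefficients=np.array([2.0]), std_errors=np.array([1.0]),
            loglik=0.0, loglik_null=0.0, converged=True, monotone_flag=False,
            n_iter=1, n_events=3,
        )
        pi = e.prognostic_index(fit, five_subject_cohort)
        np.testing.assert_allclose(pi, 2.0 * five_subject_cohort.covariates[:, 0])
        fit.coefficients = np.array([0.0])
        np.testing.assert_allclose(e.prognostic_index(fit, five_subject_cohort), 0.0)

    def test_affine_shift_changes_pi_by_constant(self, rng):
        x = rng.standard_normal((20, 2))
        coh = Cohort(x, np.arange(1.0, 21.0), np.ones(20, dtype=int), ["a", "b"])
        fit = CoxFit(
            names=["a", "b"], coefficients=np.array([1.5, -0.5]),
            std_errors=np.array([1.0, 1.0]), loglik=0.0, loglik_null=0.0,
            converged=True, monotone_flag=False, n_iter=1, n_events=20,
        )
        pi = e.prognostic_index(fit, coh)
        shifted = Cohort(x + np.array([2.0, 3.0]), coh.time, coh.event, ["a", "b"])
        pi2 = e.prognostic_index(fit, shifted)
        np.testing.assert_allclose(pi2 - pi, (pi2 - pi)[0])
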
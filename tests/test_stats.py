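"""t-tests, chi-squared, Pearson correlation, logistic regression and the
descriptive case/control table."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from plaquantify import (
    build_table1,
    chi_squared_test,
    logistic_fit,
    odds_ratio_from_beta,
    pearson_r,
    percent_difference,
    t_test_from_samples,
    t_test_two_sample,
)
from plaquantify.errors import DataError, SeparationError
from plaquantify.pipeline import summaries_from_frame
from plaquantify.synthetic_data import CohortSimConfig, simulate_cohort_frame


class TestTTest:
    def test_identical_groups_null(self):
        t, df, p = t_test_two_sample(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)
        assert df == 20

    def test_agrees_with_scipy_summary_route(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            n1, n2 = rng.integers(3, 50, 2)
            t, df, p = t_test_two_sample(m1, s1, int(n1), m2, s2, int(n2))
            ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_raw_sample_route_matches_summary_route(self, rng):
        x = rng.normal(3, 2, 25)
        y = rng.normal(2.5, 2.2, 30)
        assert t_test_from_samples(x, y) == t_test_two_sample(
            x.mean(), x.std(ddof=1), 25, y.mean(), y.std(ddof=1), 30
        )

    def test_p_matches_numerical_integration_oracle(self):
        t, df, p = t_test_two_sample(25.50, 17.45, 51, 20.58, 14.39, 40)
        tail, _ = integrate.quad(lambda u: sps.t.pdf(u, df), abs(t), np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-6)

    def test_zero_variance_equal_means_warns(self):
        with pytest.warns(UserWarning):
            _, _, p = t_test_two_sample(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert p == 1.0

    def test_tiny_group_rejected(self):
        with pytest.raises(DataError):
            t_test_two_sample(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestChiSquared:
    def test_identical_proportions_null(self):
        stat, df, p = chi_squared_test([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_random_2x3_matches_cellwise_oracle(self, rng):
        table = rng.integers(1, 40, (2, 3)).astype(float)
        stat, df, _ = chi_squared_test(table)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())
        assert df == 2

    def test_p_matches_numerical_integration_oracle(self):
        stat, df, p = chi_squared_test([[42, 9], [33, 7]])
        tail, _ = integrate.quad(lambda u: sps.chi2.pdf(u, df), stat, np.inf)
        assert p == pytest.approx(tail, abs=1e-6)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DataError):
            chi_squared_test([[0, 5], [0, 7]])


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]).r == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        r = pearson_r(x, y).r
        xm, ym = x - x.mean(), y - y.mean()
        direct = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(direct)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHelpers:
    def test_percent_difference_uses_larger_mean(self):
        assert percent_difference(25.50, 20.58) == pytest.approx(19.294, abs=1e-3)
        assert percent_difference(65.00, 68.70) == pytest.approx(5.386, abs=1e-3)

    def test_odds_ratio_with_ci(self):
        or_, lo, hi = odds_ratio_from_beta(-0.042, 0.019)
        assert or_ == pytest.approx(0.959, abs=5e-4)
        assert lo == pytest.approx(np.exp(-0.042 - 1.96 * 0.019))
        assert hi == pytest.approx(np.exp(-0.042 + 1.96 * 0.019))


def _logistic_data(rng, n=400, betas=(0.8, -0.5), intercept=-0.2):
    X = pd.DataFrame({f"x{i}": rng.normal(0, 1, n) for i in range(len(betas))})
    lp = intercept + X.to_numpy() @ np.array(betas)
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return y, X


class TestLogisticFit:
    def test_result_identities(self, rng):
        y, X = _logistic_data(rng)
        res = logistic_fit(y, X)
        for k in res.predictors:
            assert res.odds_ratio[k] == pytest.approx(np.exp(res.beta[k]), rel=1e-9)
            assert res.ci_lower[k] == pytest.approx(
                np.exp(res.beta[k] - 1.96 * res.std_error[k])
            )
            assert res.ci_upper[k] == pytest.approx(
                np.exp(res.beta[k] + 1.96 * res.std_error[k])
            )
            assert res.ci_lower[k] <= res.odds_ratio[k] <= res.ci_upper[k]
            z = res.beta[k] / res.std_error[k]
            assert res.wald_p[k] == pytest.approx(2 * sps.norm.sf(abs(z)))
        assert res.converged

    def test_recovers_known_coefficients(self, rng):
        y, X = _logistic_data(rng, n=4000, betas=(0.8, -0.5), intercept=-0.2)
        res = logistic_fit(y, X)
        assert res.beta["x0"] == pytest.approx(0.8, abs=0.15)
        assert res.beta["x1"] == pytest.approx(-0.5, abs=0.15)

    def test_one_class_outcome_rejected(self, rng):
        _, X = _logistic_data(rng, n=50)
        with pytest.raises(DataError):
            logistic_fit(np.ones(50, dtype=int), X)

    def test_complete_separation_names_predictor(self):
        X = pd.DataFrame({"sep": np.r_[np.zeros(20), np.ones(20)],
                          "noise": np.linspace(-1, 1, 40)})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.raises(SeparationError) as exc:
            logistic_fit(y, X)
        assert exc.value.predictor == "sep"


@pytest.fixture(scope="module")
def summaries():
    frame = simulate_cohort_frame(
        CohortSimConfig(n_case=600, n_control=500, mode="stratified", seed=11)
    )
    return summaries_from_frame(frame)


class TestTable1:
    def test_moments_match_generator_targets(self, summaries):
        rows = {r.variable: r for r in build_table1(summaries)}
        cov = rows["Mean plaque coverage (%)"]
        # the oracle is the analytic mean of the truncated-normal coverage
        # marginal the generator draws, not the parent mean
        def trunc_mean(m, s):
            a, b = (0 - m) / s, (100 - m) / s
            return sps.truncnorm(a, b, loc=m, scale=s).mean()

        assert cov.case_stat[0] == pytest.approx(trunc_mean(25.50, 17.45), abs=1.5)
        assert cov.control_stat[0] == pytest.approx(trunc_mean(20.58, 14.39), abs=1.5)
        age = rows["Mean maternal age (years)"]
        assert age.case_stat[0] == pytest.approx(28.69, abs=1.0)
        assert age.control_stat[0] == pytest.approx(30.78, abs=1.0)

    def test_categorical_percentages_sum_to_100(self, summaries):
        rows = build_table1(summaries)
        for prefix in ("Smoking status", "Maternal age:", "BMI category"):
            pcts_case = [r.case_stat[1] for r in rows if r.variable.startswith(prefix)]
            if pcts_case:
                assert sum(pcts_case) == pytest.approx(100, abs=1)

    def test_single_group_rejected(self, summaries):
        only_cases = [s for s in summaries if s.group == "case"]
        with pytest.raises(DataError):
            build_table1(only_cases)
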
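"""Unadjusted 2x2 analysis and Firth-penalized logistic regression."""

import numpy as np
import pytest
from scipy.special import expit

from azfcnv import (
    ContingencyTable,
    assoc_with_covariates,
    firth_from_table,
    fit_firth,
    unadjusted_or,
)
from azfcnv.errors import CollinearDesignError


def grid_maximize_pll(a, b, c, d, lo=-10.0, hi=10.0, levels=6, width=41):
    """Brute-force nested-grid maximizer of the Firth-penalized likelihood
    for a 2x2 table, independent of the package's Newton solver.

    Model: logit P(case) = b0 + b1 * carrier, with cell counts
    a (case/carrier), b (case/non), c (control/carrier), d (control/non).
    """

    def pll(b0, b1):
        # grouped Bernoulli log-likelihood
        eta1, eta0 = b0 + b1, b0  # carrier, non-carrier linear predictors
        p1, p0 = expit(eta1), expit(eta0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                a * np.log(p1)
                + c * np.log(1 - p1)
                + b * np.log(p0)
                + d * np.log(1 - p0)
            )
        # Fisher information determinant for the [1, x] design with x in
        # {0,1}: (sum w)(sum w x^2) - (sum w x)^2 = w1*w0
        w1, w0 = (a + c) * p1 * (1 - p1), (b + d) * p0 * (1 - p0)
        det = w1 * w0
        with np.errstate(divide="ignore"):
            return ll + 0.5 * np.log(det)

    c0, c1 = 0.0, 0.0
    span0, span1 = hi - lo, hi - lo
    b0g = np.linspace(lo, hi, width)
    b1g = np.linspace(lo, hi, width)
    for _ in range(levels):
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        vals = pll(B0, B1)
        vals = np.where(np.isfinite(vals), vals, -np.inf)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        c0, c1 = b0g[i], b1g[j]
        span0 = (b0g[1] - b0g[0]) * 4
        span1 = (b1g[1] - b1g[0]) * 4
        b0g = np.linspace(c0 - span0, c0 + span0, width)
        b1g = np.linspace(c1 - span1, c1 + span1, width)
    return c0, c1


class TestUnadjusted:
    def test_symmetric_table_gives_unit_odds_ratio(self):
        r = unadjusted_or(ContingencyTable(10, 90, 10, 90))
        assert r.or_point == 1.0

    def test_zero_cell_flags_firth(self):
        r = unadjusted_or(ContingencyTable(0, 100, 5, 95))
        assert r.or_point is None
        assert "zero_cell_use_firth" in r.flags

    def test_ci_brackets_the_point_estimate(self):
        r = unadjusted_or(ContingencyTable(38, 1546, 12, 635))
        assert r.ci95[0] < r.or_point < r.ci95[1]


class TestFirthCore:
    def test_balanced_symmetric_data_gives_zero_effect(self):
        fit = firth_from_table(ContingencyTable(10, 90, 10, 90))
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.or_adjusted == pytest.approx(1.0, abs=1e-8)

    def test_zero_cell_yields_finite_positive_effect_matching_grid(self):
        """5/100 carriers among cases, 0/100 among controls: ML diverges,
        the penalized estimate is finite and matches the grid maximizer."""
        t = ContingencyTable(a=5, b=95, c=0, d=100)
        fit = firth_from_table(t)
        assert fit.converged
        assert np.all(np.isfinite(fit.coefficients))
        assert fit.coefficients[1] > 0
        g0, g1 = grid_maximize_pll(5, 95, 0, 100)
        assert fit.coefficients[0] == pytest.approx(g0, abs=1e-3)
        assert fit.coefficients[1] == pytest.approx(g1, abs=1e-3)

    def test_complete_separation_stays_finite(self):
        # carrier status perfectly predicts outcome
        X = np.column_stack([np.ones(40), np.repeat([0.0, 1.0], 20)])
        y = np.repeat([0.0, 1.0], 20)
        fit = fit_firth(X, y)
        assert np.all(np.isfinite(fit.coefficients))
        assert np.isfinite(fit.or_adjusted)
        assert fit.ci95[0] > 0 and np.isfinite(fit.ci95[1])

    def test_weighted_fit_equals_expanded_fit(self):
        t = ContingencyTable(7, 53, 3, 87)
        agg = firth_from_table(t)
        rows = (
            [(1.0, 1.0)] * 7 + [(1.0, 0.0)] * 53 + [(0.0, 1.0)] * 3 + [(0.0, 0.0)] * 87
        )
        y = np.array([r[0] for r in rows])
        X = np.column_stack([np.ones(len(rows)), [r[1] for r in rows]])
        exp = fit_firth(X, y)
        assert agg.coefficients == pytest.approx(exp.coefficients, abs=1e-9)
        assert agg.penalized_loglik == pytest.approx(exp.penalized_loglik, abs=1e-9)

    def test_penalized_likelihood_never_below_start(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 60
            x = rng.binomial(1, 0.3, n).astype(float)
            y = rng.binomial(1, expit(-1 + 1.2 * x)).astype(float)
            if y.min() == y.max():
                continue
            X = np.column_stack([np.ones(n), x])
            fit = fit_firth(X, y, ci_method="wald")
            # pll at the optimum dominates pll at the zero start
            from azfcnv.association import _pll

            assert fit.penalized_loglik >= _pll(X, y, np.ones(n), np.zeros(2)) - 1e-9

    def test_large_sample_agrees_with_plain_maximum_likelihood(self):
        """With n=2000 and no separation the Jeffreys penalty is negligible:
        Firth and ordinary ML agree to 2 decimals (statsmodels as oracle)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        n = 2000
        x = rng.binomial(1, 0.4, n).astype(float)
        y = rng.binomial(1, expit(-0.5 + np.log(2) * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_firth(X, y, ci_method="wald")
        ml = sm.Logit(y, X).fit(disp=0)
        assert fit.coefficients == pytest.approx(ml.params, abs=5e-3)

    def test_collinear_design_is_named(self):
        X = np.column_stack([np.ones(30), np.arange(30.0), np.arange(30.0) * 2])
        y = (np.arange(30) % 2).astype(float)
        with pytest.raises(CollinearDesignError, match="column"):
            fit_firth(X, y)

    def test_profile_ci_is_wider_than_wald_under_sparsity(self):
        t = ContingencyTable(3, 197, 1, 199)
        prof = firth_from_table(t, ci_method="profile")
        wald = firth_from_table(t, ci_method="wald")
        assert prof.ci_method == "profile"
        # both cover the point estimate
        for fit in (prof, wald):
            assert fit.ci95[0] < fit.or_adjusted < fit.ci95[1]


class TestCovariateAdjustment:
    def _table(self, carrier, phenotype, covs):
        import pandas as pd

        data = {
            "sample_id": [f"s{i}" for i in range(len(carrier))],
            "carrier": carrier,
            "phenotype": phenotype,
        }
        for j, col in enumerate(covs, start=1):
            data[f"cov{j}"] = col
        return pd.DataFrame(data)

    def test_all_zero_covariates_match_covariate_free_fit(self):
        rng = np.random.default_rng(3)
        carrier = rng.binomial(1, 0.3, 300)
        phenotype = rng.binomial(1, expit(-0.5 + 0.8 * carrier))
        tbl = self._table(carrier, phenotype, [np.zeros(300)])
        with_cov = assoc_with_covariates(tbl, 1, ci_method="wald")
        without = assoc_with_covariates(self._table(carrier, phenotype, []), 0,
                                        ci_method="wald")
        assert with_cov.coefficients[:2] == pytest.approx(
            without.coefficients[:2], abs=1e-9
        )

    def test_missing_covariate_values_name_the_samples(self):
        tbl = self._table([0, 1, 0, 1], [0, 0, 1, 1], [np.array([0.1, np.nan, 0.2, 0.3])])
        with pytest.raises(ValueError, match="s1"):
            assoc_with_covariates(tbl, 1)

    def test_adjustment_removes_confounding(self):
        """A confounder driving both carrier status and outcome biases the
        unadjusted OR; adjusting recovers the generative effect better."""
        rng = np.random.default_rng(29)
        n = 6000
        z = rng.normal(size=n)
        carrier = rng.binomial(1, expit(-2.0 + 1.5 * z)).astype(float)
        true_log_or = np.log(1.5)
        y = rng.binomial(1, expit(-1.5 + true_log_or * carrier + 1.2 * z)).astype(float)
        tbl = self._table(carrier, y, [z])
        adjusted = assoc_with_covariates(tbl, 1, ci_method="wald")
        a = int(((carrier == 1) & (y == 1)).sum())
        b = int(((carrier == 0) & (y == 1)).sum())
        c = int(((carrier == 1) & (y == 0)).sum())
        d = int(((carrier == 0) & (y == 0)).sum())
        crude = unadjusted_or(ContingencyTable(a, b, c, d)).or_point
        assert abs(np.log(adjusted.or_adjusted) - true_log_or) < abs(
            np.log(crude) - true_log_or
        )
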
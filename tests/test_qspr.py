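import math

import numpy as np
import pytest

from domentropy import (
    entropy_table,
    fit_linear,
    fit_multilinear,
    property_table,
    qspr_report,
)
from domentropy.qspr import MULTILINEAR_PREDICTORS, PROPERTY_COLUMNS


@pytest.fixture(scope="module")
def entropies():
    return entropy_table()


class TestPropertyTable:
    def test_shape_and_columns(self):
        t = property_table()
        assert t.shape == (29, 10)
        assert tuple(t.columns) == PROPERTY_COLUMNS
        assert np.isfinite(t.to_numpy()).all()

    def test_spot_values(self):
        t = property_table()
        assert t.loc["BH2", "PE"] == 13.6832
        assert t.loc["BH1", "MW"] == 78.11
        assert t.loc["BH29", "MW"] == 300.4

    def test_pe_increases_along_acene_series(self):
        t = property_table()
        acenes = ["BH1", "BH2", "BH3", "BH5", "BH11", "BH28"]
        pe = t.loc[acenes, "PE"].to_numpy()
        assert (np.diff(pe) > 0).all()


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(5, dtype=float)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.r == pytest.approx(1.0)
        assert fit.se == pytest.approx(0.0, abs=1e-10)
        assert fit.slopes[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_against_normal_equations(self):
        # 5-point hand dataset; closed-form least squares as oracle
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 6.0, 8.0])
        beta = (len(x) * (x * y).sum() - x.sum() * y.sum()) / (
            len(x) * (x * x).sum() - x.sum() ** 2
        )
        alpha = y.mean() - beta * x.mean()
        fit = fit_linear(x, y)
        assert fit.slopes[0] == pytest.approx(beta)
        assert fit.intercept == pytest.approx(alpha)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_f_matches_r_identity(self, entropies):
        """F = r^2 (n-2) / (1-r^2) for every simple fit (n = 29)."""
        props = property_table()
        for ent in ["E_DABC", "E_DM3*"]:
            for prop in ["BP", "PE", "C"]:
                fit = fit_linear(entropies[ent], props[prop], ent, prop)
                expect = fit.r**2 * (fit.n - 2) / (1 - fit.r**2)
                assert fit.f == pytest.approx(expect, rel=1e-6)

    def test_bp_on_dm3star_statistics(self, entropies):
        """The strongest boiling-point model: r about 0.975, positive slope,
        negative intercept, F above 500."""
        fit = fit_linear(entropies["E_DM3*"], property_table()["BP"])
        assert fit.r == pytest.approx(0.97518, abs=0.01)
        assert fit.slopes[0] > 0 and fit.intercept < 0
        assert fit.p < 1e-4

    def test_standardization_invariance(self, entropies):
        """Centering/scaling x leaves r, F, p unchanged."""
        x = entropies["E_DABC"].to_numpy()
        y = property_table()["PE"].to_numpy()
        a = fit_linear(x, y)
        b = fit_linear((x - x.mean()) / x.std(), y)
        assert a.r == pytest.approx(b.r, rel=1e-10)
        assert a.f == pytest.approx(b.f, rel=1e-8)
        assert a.p == pytest.approx(b.p, rel=1e-6)


class TestFitMultilinear:
    def test_exact_coefficient_recovery(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, size=(40, 5))
        y = 3 + 2 * X[:, 0] - X[:, 3]
        fit = fit_multilinear(X, y)
        assert fit.intercept == pytest.approx(3, abs=1e-8)
        assert np.allclose(fit.slopes, [2, 0, 0, -1, 0], atol=1e-8)
        assert fit.r == pytest.approx(1.0)

    def test_response_equal_to_predictor(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(30, 5))
        fit = fit_multilinear(X, X[:, 2])
        assert fit.r == pytest.approx(1.0)

    def test_residual_orthogonality(self, entropies):
        X = entropies[list(MULTILINEAR_PREDICTORS)].to_numpy()
        y = property_table()["BP"].to_numpy()
        fit = fit_multilinear(X, y, MULTILINEAR_PREDICTORS, "BP")
        resid = y - (fit.intercept + X @ np.array(fit.slopes))
        design = np.column_stack([np.ones(len(y)), X])
        assert np.abs(design.T @ resid).max() < 1e-6 * np.abs(y).sum()

    def test_collinearity_diagnostic_on_entropies(self, entropies):
        """The five entropy predictors are nearly collinear on benzenoids:
        the fit must carry a condition-number warning."""
        X = entropies[list(MULTILINEAR_PREDICTORS)].to_numpy()
        fit = fit_multilinear(X, property_table()["BP"].to_numpy())
        assert fit.condition_number > 30
        assert fit.warnings

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            fit_multilinear(np.eye(5), np.arange(5.0))


class TestReport:
    def test_full_report_dimensions(self, entropies):
        rep = qspr_report(entropies)
        assert (rep.model == "linear").sum() == 100
        assert (rep.model == "multilinear").sum() == 10

    def test_every_fit_significant(self, entropies):
        rep = qspr_report(entropies)
        assert (rep.p < 1e-4).all()
        assert (rep.r > 0.9).all()
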
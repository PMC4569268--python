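"""Quadratic surface fitting, ANOVA diagnostics and basis handling."""

import numpy as np
import pytest
from scipy import integrate, special

from codmedia import doe, rsm
from codmedia.rsm import QuadraticModel, convert_basis, fit_quadratic, surface_slice


def constant_model(c: float) -> QuadraticModel:
    return QuadraticModel(
        intercept=c,
        linear=np.zeros(5),
        interactions=np.zeros(10),
        quadratic=np.zeros(5),
        basis="uncoded",
    )


class TestPredict:
    def test_published_model_at_center(self, published_model, center_composition):
        assert published_model.predict(center_composition) == pytest.approx(
            3.12288, abs=5e-6
        )

    def test_published_model_at_high_soybean_star(self, published_model):
        assert published_model.predict([1.5, 0.75, 0.75, 0.025, 0.15]) == pytest.approx(
            2.93633, abs=1e-5
        )

    def test_constant_model(self, center_composition):
        model = constant_model(4.2)
        assert model.predict(center_composition) == pytest.approx(4.2)
        assert model.predict(np.zeros(5)) == pytest.approx(4.2)

    def test_length_mismatch_rejected(self, published_model):
        with pytest.raises(ValueError, match="length"):
            published_model.predict([1.0, 2.0])


class TestFit:
    def test_noiseless_recovery_is_exact(self, published_model):
        """OLS on responses generated exactly by a known quadratic recovers
        every coefficient to machine precision."""
        design = doe.generate_ccd(doe.cod_factors(), n_center=10)
        design = design.with_observed(published_model.predict(design.uncoded))
        model, diag = fit_quadratic(design, basis="uncoded")
        np.testing.assert_allclose(
            model.coefficient_vector(),
            published_model.coefficient_vector(),
            rtol=1e-8,
        )
        assert diag.r_squared == pytest.approx(1.0)

    def test_fixture_refit_diagnostics(self, paper_design):
        _, diag = fit_quadratic(paper_design, basis="uncoded")
        assert diag.r_squared == pytest.approx(0.920067, abs=1e-5)
        assert diag.r == pytest.approx(np.sqrt(diag.r_squared))
        assert diag.dof_model == 20
        assert diag.dof_error == 15

    def test_residuals_sum_to_zero(self, paper_design):
        _, diag = fit_quadratic(paper_design, basis="uncoded")
        assert abs(diag.residuals.sum()) < 1e-10

    def test_refit_interactions_match_published_equation(self, paper_design, published_model):
        """The interaction coefficients are identified by the factorial
        contrasts alone and agree with the published equation exactly."""
        model, _ = fit_quadratic(paper_design, basis="uncoded")
        np.testing.assert_allclose(
            model.interactions, published_model.interactions, rtol=1e-5
        )

    def test_agrees_with_statsmodels_reference(self, paper_design):
        sm = pytest.importorskip("statsmodels.api")
        M = rsm.model_matrix(paper_design.uncoded)
        res = sm.OLS(paper_design.observed, M).fit()
        model, diag = fit_quadratic(paper_design, basis="uncoded")
        np.testing.assert_allclose(model.coefficient_vector(), res.params, rtol=1e-7)
        assert diag.r_squared == pytest.approx(res.rsquared, abs=1e-10)
        assert diag.f_overall == pytest.approx(res.fvalue, rel=1e-8)

    def test_missing_responses_rejected(self):
        design = doe.generate_ccd(doe.cod_factors(), n_center=10)
        with pytest.raises(ValueError, match="missing"):
            fit_quadratic(design)

    def test_singular_design_names_collinear_terms(self, published_model):
        # two identical factors make their columns collinear
        factors = [
            doe.FactorSpec("a", 1.0, 0.5),
            doe.FactorSpec("b", 1.0, 0.5),
            doe.FactorSpec("c", 1.0, 0.5),
        ]
        design = doe.generate_ccd(factors, n_center=3, fraction="full")
        df = design.df.copy()
        df["b"] = df["a"]  # duplicate column
        df["observed"] = 1.0
        bad = doe.DesignTable(factors, df)
        with pytest.raises(rsm.SingularDesignError, match="collinear"):
            fit_quadratic(bad, basis="uncoded")


class TestBasisConversion:
    def test_fit_in_coded_predicts_like_uncoded(self, paper_design):
        m_unc, _ = fit_quadratic(paper_design, basis="uncoded")
        m_cod, _ = fit_quadratic(paper_design, basis="coded")
        converted = convert_basis(m_cod, paper_design.factors, "uncoded")
        np.testing.assert_allclose(
            converted.predict(paper_design.uncoded),
            m_unc.predict(paper_design.uncoded),
            atol=1e-10,
        )

    def test_roundtrip_preserves_coefficients(self, published_model):
        factors = doe.cod_factors()
        there = convert_basis(published_model, factors, "coded")
        back = convert_basis(there, factors, "uncoded")
        np.testing.assert_allclose(
            back.coefficient_vector(), published_model.coefficient_vector(), atol=1e-8
        )


def f_sf_by_quadrature(f_val: float, d1: int, d2: int) -> float:
    """Upper tail of the F distribution by numerical integration of the
    density written from first principles (independent of scipy.stats)."""

    def density(x):
        num = (d1 * x) ** (d1 / 2) * d2 ** (d2 / 2)
        den = (d1 * x + d2) ** ((d1 + d2) / 2)
        return num / den / (x * special.beta(d1 / 2, d2 / 2))

    val, _ = integrate.quad(density, f_val, np.inf, limit=200)
    return val


class TestAnova:
    def test_maltose_mgso4_interaction_matches_published_table(self, paper_design):
        model, _ = fit_quadratic(paper_design, basis="uncoded")
        table = rsm.anova_table(model, paper_design)
        row = table.loc["maltose:mgso4"]
        assert row["sum_of_squares"] == pytest.approx(6.5536, abs=1e-3)
        assert row["f_value"] == pytest.approx(47.617, abs=0.05)
        assert row["p_value"] == pytest.approx(5.06e-6, rel=0.02)

    def test_soybean_linear_matches_published_table(self, paper_design):
        model, _ = fit_quadratic(paper_design, basis="uncoded")
        table = rsm.anova_table(model, paper_design)
        row = table.loc["soybean"]
        assert row["sum_of_squares"] == pytest.approx(1.112298, abs=1e-4)
        assert row["f_value"] == pytest.approx(8.0817, abs=0.01)
        assert row["p_value"] == pytest.approx(0.012344, abs=1e-4)

    def test_p_values_agree_with_quadrature_oracle(self, paper_design):
        model, _ = fit_quadratic(paper_design, basis="uncoded")
        table = rsm.anova_table(model, paper_design)
        for term in ("soybean", "maltose:mgso4", "nacl^2"):
            row = table.loc[term]
            expected = f_sf_by_quadrature(row["f_value"], 1, 15)
            assert row["p_value"] == pytest.approx(expected, abs=1e-6)

    def test_orthogonal_zero_coefficient_term_has_zero_ss(self):
        """A response built without any x1 contribution on an orthogonal
        coded design yields SS = F = 0 for the x1 term."""
        factors = [doe.FactorSpec(f"f{i}", 0.0, 1.0, alpha=2.0) for i in range(3)]
        design = doe.generate_ccd(factors, n_center=5, fraction="full")
        X = design.coded
        y = 1.0 + 2.0 * X[:, 1] - 0.5 * X[:, 2] + 0.3 * X[:, 1] * X[:, 2]
        design = design.with_observed(y)
        model, _ = fit_quadratic(design, basis="coded")
        table = rsm.anova_table(model, design)
        assert table.loc["f0", "sum_of_squares"] == pytest.approx(0.0, abs=1e-16)
        assert table.loc["f0", "f_value"] == pytest.approx(0.0, abs=1e-10)


class TestSurfaceSlice:
    def test_center_node_equals_center_prediction(self, published_model):
        factors = doe.cod_factors()
        grid = surface_slice(published_model, 0, 4, factors, grid_n=21)
        # the lattice node nearest the all-center composition predicts the
        # published center-point value (the star box is a hair off-center,
        # so the node sits within half a grid step of it)
        dist = (grid["soybean"] - 0.75).abs() + (grid["nacl"] - 0.15).abs()
        nearest = grid.loc[dist.idxmin()]
        assert nearest["predicted"] == pytest.approx(3.12288, abs=2e-3)

    def test_constant_model_gives_flat_grid(self):
        grid = surface_slice(constant_model(2.5), 1, 2, doe.cod_factors(), grid_n=5)
        np.testing.assert_allclose(grid["predicted"], 2.5)

    def test_grid_max_dominates_center_prediction(self, published_model):
        factors = doe.cod_factors()
        grid = surface_slice(published_model, 2, 3, factors, grid_n=41)
        assert grid["predicted"].max() >= published_model.predict(
            [0.75, 0.75, 0.75, 0.025, 0.15]
        )

    def test_same_axis_rejected(self, published_model):
        with pytest.raises(ValueError):
            surface_slice(published_model, 1, 1, doe.cod_factors())


class TestSerialization:
    def test_json_roundtrip(self, published_model, tmp_path):
        path = tmp_path / "model.json"
        published_model.to_json(path)
        back = QuadraticModel.from_json(path)
        np.testing.assert_allclose(
            back.coefficient_vector(), published_model.coefficient_vector()
        )
        assert back.basis == "uncoded"
        assert back.factor_names == published_model.factor_names
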
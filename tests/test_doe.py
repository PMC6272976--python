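"""Unit and property tests for screening and response-surface analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fermkin as fk
from fermkin.doe import (
    DesignError,
    InvalidSpecError,
    SingularDesignError,
    _model_matrix,
    _quadratic_terms,
)
from fermkin.synthdata import box_behnken


# ---------------------------------------------------------------------------
# factor coding
# ---------------------------------------------------------------------------

class TestFactorCoding:
    @pytest.mark.parametrize(
        "center, halfwidth, real, coded",
        [
            (2.0, 1.0, 1.76, -0.24),   # kappa-carrageenan at the EA optimum
            (2.0, 1.0, 2.0, 0.0),      # center maps to coded zero
            (20.0, 5.0, 25.0, 1.0),    # NaCl high level
        ],
    )
    def test_encode_examples(self, center, halfwidth, real, coded):
        spec = fk.FactorSpec("f", center=center, halfwidth=halfwidth)
        assert fk.encode_levels(spec, real) == pytest.approx(coded)

    @settings(max_examples=100, derandomize=True)
    @given(
        center=st.floats(-100, 100),
        halfwidth=st.floats(0.01, 50),
        real=st.floats(-1000, 1000),
    )
    def test_decode_inverts_encode(self, center, halfwidth, real):
        spec = fk.FactorSpec("f", center=center, halfwidth=halfwidth)
        assert fk.decode_levels(spec, fk.encode_levels(spec, real)) == pytest.approx(
            real, abs=1e-9
        )

    @pytest.mark.parametrize("halfwidth", [0.0, -1.0, float("nan")])
    def test_invalid_halfwidth_rejected(self, halfwidth):
        with pytest.raises(InvalidSpecError):
            fk.FactorSpec("f", center=1.0, halfwidth=halfwidth)

    def test_two_level_constructor(self):
        spec = fk.FactorSpec.from_two_levels("NaCl", low=10.0, high=25.0)
        assert fk.encode_levels(spec, 10.0) == pytest.approx(-1.0)
        assert fk.encode_levels(spec, 25.0) == pytest.approx(1.0)
        with pytest.raises(InvalidSpecError):
            fk.FactorSpec.from_two_levels("bad", low=5.0, high=5.0)


# ---------------------------------------------------------------------------
# Plackett-Burman screening
# ---------------------------------------------------------------------------

class TestPBEffects:
    @pytest.mark.parametrize(
        "response, factor, effect, coefficient",
        [
            ("EA", "A", 73.66, 36.83),   # kappa-carrageenan dominates EA
            ("EA", "E", 40.57, 20.29),   # NaCl boosts EA
            ("BM", "E", -0.044, None),   # but suppresses biomass
        ],
    )
    def test_fixture_effects_match_printed_table(
        self, pb_table, response, factor, effect, coefficient
    ):
        result = fk.pb_effects(pb_table, response)
        assert result.factors.loc[factor, "effect"] == pytest.approx(effect, abs=0.005)
        if coefficient is not None:
            assert result.factors.loc[factor, "coefficient"] == pytest.approx(
                coefficient, abs=0.005
            )

    def test_dummy_effects_match_printed_table(self, pb_table):
        result = fk.pb_effects(pb_table, "EA")
        assert result.dummy_effects.to_numpy() == pytest.approx(
            [-4.20, -2.95, 2.69], abs=0.01
        )
        assert result.error_df == 3

    def test_effects_equal_twice_ols_coefficients(self, pb_table):
        """Contrast effects equal 2x the OLS slopes of the main-effects model
        (independent oracle: direct least squares on the coded matrix)."""
        y = pb_table.response("EA")
        coded = pb_table.coded.to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), coded])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        result = fk.pb_effects(pb_table, "EA")
        all_effects = pd.concat(
            [result.factors["effect"], result.dummy_effects]
        ).reindex(pb_table.coded.columns)
        np.testing.assert_allclose(all_effects.to_numpy(), 2.0 * beta[1:], atol=1e-9)

    def test_significance_flag_matches_t_limit(self, pb_table):
        result = fk.pb_effects(pb_table, "EA", t_limit=2.36462)
        assert result.t_limit == 2.36462
        for _, row in result.factors.iterrows():
            assert row["significant"] == (abs(row["t_value"]) > 2.36462)
        # the four medium factors called significant by the screening
        assert set(result.factors.index[result.factors["significant"]]) == {
            "A", "B", "C", "E"
        }

    def test_constant_response_gives_zero_effects(self, pb_table):
        table = fk.DesignTable(
            coded=pb_table.coded,
            responses=pd.DataFrame({"Y": np.full(pb_table.n_runs, 7.0)}),
            dummy_columns=pb_table.dummy_columns,
        )
        result = fk.pb_effects(table, "Y")
        assert result.factors["effect"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_column_rejected(self, pb_table):
        coded = pb_table.coded.copy()
        coded.iloc[0, 0] = -coded.iloc[0, 0]
        table = fk.DesignTable(
            coded=coded,
            responses=pb_table.responses,
            dummy_columns=pb_table.dummy_columns,
        )
        with pytest.raises(DesignError, match="unbalanced"):
            fk.pb_effects(table, "EA")

    def test_no_dummies_warns_and_omits_t(self, pb_table):
        table = fk.DesignTable(coded=pb_table.coded, responses=pb_table.responses)
        with pytest.warns(UserWarning, match="dummy"):
            result = fk.pb_effects(table, "EA")
        assert np.isnan(result.factors["t_value"]).all()


# ---------------------------------------------------------------------------
# quadratic response-surface fit
# ---------------------------------------------------------------------------

def _random_quadratic_table(seed: int, n_factors: int = 4):
    rng = np.random.default_rng(seed)
    design = box_behnken(n_factors)
    names = list(design.columns)
    terms = _quadratic_terms(names)
    truth = pd.Series(rng.normal(0, 10, len(terms)), index=[t[0] for t in terms])
    X = _model_matrix(design.to_numpy(dtype=float), terms)
    y = X @ truth.to_numpy()
    table = fk.DesignTable(coded=design, responses=pd.DataFrame({"Y": y}))
    return table, truth


class TestQuadraticFit:
    def test_printed_coefficients_reproduced(self, ea_fit, bm_fit):
        assert ea_fit.intercept == pytest.approx(266.19, abs=0.005)
        assert ea_fit.coefficients["X1"] == pytest.approx(-11.23, abs=0.005)
        assert ea_fit.coefficients["X3:X4"] == pytest.approx(-44.73, abs=0.005)
        assert bm_fit.intercept == pytest.approx(0.52, abs=0.005)
        assert bm_fit.coefficients["X2"] == pytest.approx(-0.018, abs=0.0005)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noiseless_roundtrip_recovers_truth(self, seed):
        """Any response generated exactly from a quadratic on the design is
        recovered to machine precision with R^2 = 1."""
        table, truth = _random_quadratic_table(seed)
        fit = fk.fit_quadratic(table, "Y")
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), truth.to_numpy(), atol=1e-8
        )
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_residuals_orthogonal_to_model_columns(self, ea_fit, bbd_table):
        coded = bbd_table.coded[ea_fit.factor_names].to_numpy(dtype=float)
        X = _model_matrix(coded, _quadratic_terms(ea_fit.factor_names))
        assert np.max(np.abs(X.T @ ea_fit.residuals)) < 1e-8

    def test_prediction_at_origin_is_intercept(self, ea_fit):
        assert ea_fit.predict([0, 0, 0, 0]) == pytest.approx(ea_fit.intercept)

    def test_collinear_design_raises_with_column_names(self):
        design = box_behnken(4)
        design["X2"] = design["X1"]  # force collinearity
        table = fk.DesignTable(
            coded=design, responses=pd.DataFrame({"Y": np.arange(len(design), dtype=float)})
        )
        with pytest.raises(SingularDesignError, match="collinear"):
            fk.fit_quadratic(table, "Y")

    def test_too_few_runs_raises(self):
        design = box_behnken(4).head(10)
        table = fk.DesignTable(
            coded=design, responses=pd.DataFrame({"Y": np.arange(10.0)})
        )
        with pytest.raises(DesignError):
            fk.fit_quadratic(table, "Y")


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestAnova:
    def test_sum_of_squares_decomposition(self, ea_fit, bbd_table):
        an = fk.anova_quadratic(ea_fit, bbd_table).table
        assert an.loc["model", "SS"] + an.loc["residual", "SS"] == pytest.approx(
            an.loc["total", "SS"], rel=1e-12
        )
        assert an.loc["lack-of-fit", "SS"] + an.loc["pure-error", "SS"] == pytest.approx(
            an.loc["residual", "SS"], rel=1e-12
        )
        assert an.loc["model", "df"] + an.loc["residual", "df"] == an.loc["total", "df"]
        assert (
            an.loc["lack-of-fit", "df"] + an.loc["pure-error", "df"]
            == an.loc["residual", "df"]
        )

    def test_pure_error_from_center_replicates(self, ea_fit, bbd_table):
        """Pure error equals the within-group SS of the five center runs."""
        center = bbd_table.response("EA")[-5:]
        expected = float(np.sum((center - center.mean()) ** 2))
        an = fk.anova_quadratic(ea_fit, bbd_table).table
        assert an.loc["pure-error", "SS"] == pytest.approx(expected, rel=1e-12)
        assert an.loc["pure-error", "df"] == 4

    def test_r_squared_consistent_with_anova(self, ea_fit, bbd_table):
        an = fk.anova_quadratic(ea_fit, bbd_table).table
        r2 = 1.0 - an.loc["residual", "SS"] / an.loc["total", "SS"]
        assert ea_fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_linear_term_ss_match_orthogonal_formula(self, ea_fit, bbd_table):
        """On the orthogonal BBD basis the partial SS of a linear term is
        coefficient^2 times the column sum of squares."""
        an = fk.anova_quadratic(ea_fit, bbd_table).table
        coded = bbd_table.coded.to_numpy(dtype=float)
        for j, name in enumerate(ea_fit.factor_names):
            expected = ea_fit.coefficients[name] ** 2 * np.sum(coded[:, j] ** 2)
            assert an.loc[name, "SS"] == pytest.approx(expected, rel=1e-9)

    def test_noiseless_response_zero_residual(self):
        table, _ = _random_quadratic_table(3)
        fit = fk.fit_quadratic(table, "Y")
        an = fk.anova_quadratic(fit, table).table
        assert an.loc["residual", "SS"] == pytest.approx(0.0, abs=1e-8)

    def test_without_replicates_warns(self):
        table, _ = _random_quadratic_table(4)
        # 24 edge runs plus a single (unreplicated) center run: the model is
        # identifiable but pure error cannot be estimated
        no_reps = fk.DesignTable(
            coded=table.coded.head(25), responses=table.responses.head(25)
        )
        fit = fk.fit_quadratic(no_reps, "Y")
        with pytest.warns(UserWarning, match="replicate"):
            an = fk.anova_quadratic(fit, no_reps)
        assert "lack-of-fit" not in an.table.index


# ---------------------------------------------------------------------------
# surface optimization
# ---------------------------------------------------------------------------

def _fit_from_coefficients(coeffs: dict, names) -> fk.QuadraticFit:
    terms = _quadratic_terms(list(names))
    series = pd.Series({lab: coeffs.get(lab, 0.0) for lab, _ in terms})
    return fk.QuadraticFit(
        response="Y",
        factor_names=list(names),
        coefficients=series,
        r_squared=1.0,
        fitted_values=np.zeros(1),
        residuals=np.zeros(1),
        n_runs=len(series) + 1,
    )


class TestOptimizeQuadratic:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_closed_form_stationary_point(self, seed):
        """Interior maximum of a concave quadratic equals the solution of
        H x = -g (oracle: direct linear solve)."""
        rng = np.random.default_rng(seed)
        names = ["X1", "X2", "X3"]
        A = rng.normal(size=(3, 3))
        H = -(A @ A.T + 3 * np.eye(3))  # negative definite
        g = rng.normal(scale=0.5, size=3)
        coeffs = {"Intercept": 5.0}
        for i, n in enumerate(names):
            coeffs[n] = g[i]
            coeffs[f"{n}^2"] = H[i, i] / 2.0
        for i in range(3):
            for j in range(i + 1, 3):
                coeffs[f"{names[i]}:{names[j]}"] = H[i, j]
        fit = _fit_from_coefficients(coeffs, names)
        x_star = np.linalg.solve(H, -g)
        opt = fk.optimize_quadratic(fit, box=(-2.0, 2.0))
        if np.all(np.abs(x_star) <= 2.0):
            np.testing.assert_allclose(opt.coded_vector(), x_star, atol=1e-8)
            assert not opt.on_boundary

    def test_concave_bowl_optimum_at_origin(self):
        names = ["X1", "X2", "X3", "X4"]
        coeffs = {"Intercept": 10.0, **{f"{n}^2": -1.0 for n in names}}
        fit = _fit_from_coefficients(coeffs, names)
        opt = fk.optimize_quadratic(fit)
        np.testing.assert_allclose(opt.coded_vector(), 0.0, atol=1e-10)
        assert opt.predicted_response == pytest.approx(10.0)

    def test_linear_surface_ends_on_boundary(self):
        fit = _fit_from_coefficients({"Intercept": 0.0, "X1": 2.0, "X2": -1.0},
                                     ["X1", "X2"])
        opt = fk.optimize_quadratic(fit)
        assert opt.on_boundary
        np.testing.assert_allclose(opt.coded_vector(), [1.0, -1.0], atol=1e-6)

    def test_minimization_sense(self):
        names = ["X1", "X2"]
        fit = _fit_from_coefficients(
            {"Intercept": 3.0, "X1^2": 1.0, "X2^2": 2.0}, names
        )
        opt = fk.optimize_quadratic(fit, sense="min")
        np.testing.assert_allclose(opt.coded_vector(), 0.0, atol=1e-10)
        assert opt.predicted_response == pytest.approx(3.0)

    def test_optimum_dominates_design_runs(self, ea_fit, bbd_table):
        opt = fk.optimize_quadratic(ea_fit)
        fitted_at_runs = ea_fit.fitted_values
        assert opt.predicted_response >= fitted_at_runs.max() - 1e-9

    def test_real_unit_decoding(self, ea_fit, bbd_table):
        opt = fk.optimize_quadratic(ea_fit, factors=bbd_table.factor_specs)
        spec = bbd_table.factor_specs["X1"]
        assert opt.real_location["X1"] == pytest.approx(
            spec.decode(opt.coded_location["X1"])
        )


class TestRelativeError:
    def test_values(self):
        assert fk.relative_error(267.851, 266.84) == pytest.approx(0.00377, abs=1e-4)
        assert fk.relative_error(0.521281, 0.519) == pytest.approx(0.00438, abs=1e-4)
        assert fk.relative_error(5.0, 5.0) == 0.0

    def test_zero_prediction_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fk.relative_error(0.0, 1.0)
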
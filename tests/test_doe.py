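"""L9 design construction, effect analysis, quadratic response surfaces
and optimum selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ergolever as el
from ergolever.doe import DEFAULT_FACTORS


class TestBuildL9:
    def test_reproduces_study_design_row_for_row(self, design):
        built = el.build_l9()
        assert list(built.index) == list(design.index)
        assert np.allclose(built.to_numpy(), design.to_numpy(dtype=float))
        # spot rows: first and last experiments
        assert tuple(built.loc["E1"]) == (45.0, 0.0, -30.0)
        assert tuple(built.loc["E9"]) == (0.0, 100.0, 0.0)

    def test_orthogonality(self):
        """Every (factor, level) appears 3x; every ordered level pair of any
        two factors appears exactly once."""
        built = el.build_l9()
        for factor in built.columns:
            assert built[factor].value_counts().eq(3).all()
        for f1, f2 in itertools.combinations(built.columns, 2):
            pairs = built.groupby([f1, f2]).size()
            assert len(pairs) == 9 and pairs.eq(1).all()

    def test_wrong_factor_count_rejected(self):
        with pytest.raises(ValueError, match="3 factors"):
            el.build_l9(DEFAULT_FACTORS[:2])

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError, match="distinct levels"):
            el.FactorSpec("bad", (0.0, 0.0, 1.0))


class TestMainEffects:
    def test_reproduces_printed_main_effects(self, effects):
        printed = el.datasets.load_main_effects()
        for row in printed.itertuples():
            computed = effects.loc[(row.factor, row.level), row.muscle]
            assert computed == pytest.approx(row.mean_mvc, abs=5e-3), \
                f"{row.factor}@{row.level}/{row.muscle}"

    def test_grand_mean_conservation(self, design, mvc_table, effects):
        grand = mvc_table.mean()
        for factor in design.columns:
            level_means = effects.loc[factor]
            assert np.allclose(level_means.mean(), grand, rtol=1e-9)

    def test_constant_responses_give_constant_levels(self, design):
        flat = pd.DataFrame(7.0, index=design.index, columns=["M"])
        effects = el.main_effects(design, flat)
        assert np.allclose(effects["M"], 7.0)

    def test_missing_run_named_in_error(self, design, mvc_table):
        with pytest.raises(ValueError, match="E5"):
            el.main_effects(design, mvc_table.drop(index="E5"))


class TestInteractionGrid:
    def test_cells_are_single_runs(self, design, mvc_table):
        grids = el.interaction_grid(
            design, mvc_table, ("torso_angle_deg", "lever_distance_mm"))
        # run E1 sits at (45 deg, 0 mm); its brachioradialis MVC is the cell
        assert grids["BRD"].loc[45, 0] == pytest.approx(111.41, abs=5e-3)

    def test_margins_equal_main_effects(self, design, mvc_table, effects):
        for pair in itertools.combinations(design.columns, 2):
            grids = el.interaction_grid(design, mvc_table, pair)
            for muscle, grid in grids.items():
                assert np.allclose(grid.mean(axis=1),
                                   effects.loc[pair[0], muscle].loc[grid.index])
                assert np.allclose(grid.mean(axis=0),
                                   effects.loc[pair[1], muscle].loc[grid.columns])

    def test_constant_responses_give_flat_grid(self, design):
        flat = pd.DataFrame(3.0, index=design.index, columns=["M"])
        grids = el.interaction_grid(
            design, flat, ("torso_angle_deg", "lever_orientation_deg"))
        assert np.allclose(grids["M"].to_numpy(), 3.0)

    def test_identical_factors_rejected(self, design, mvc_table):
        with pytest.raises(ValueError, match="distinct"):
            el.interaction_grid(design, mvc_table,
                                ("torso_angle_deg", "torso_angle_deg"))


def _normal_equations(x, y):
    """Independent OLS oracle: solve X'Xb = X'y directly."""
    X = np.column_stack([np.ones_like(x), x, x**2])
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestQuadraticFit:
    def test_agrees_with_normal_equations_oracle(self, design, mvc_table):
        for factor in design.columns:
            for muscle in mvc_table.columns:
                fit = el.fit_quadratic(design, mvc_table, factor, muscle)
                b = _normal_equations(design[factor].to_numpy(dtype=float),
                                      mvc_table[muscle].to_numpy())
                assert np.allclose([fit.b0, fit.b1, fit.b2], b, rtol=1e-9)

    def test_reproduces_printed_torso_rows(self, design, mvc_table):
        bbl = el.fit_quadratic(design, mvc_table, "torso_angle_deg", "BBL")
        assert bbl.b0 == pytest.approx(38.46, abs=5e-3)
        assert bbl.b1 == pytest.approx(0.0658, abs=5e-4)
        assert bbl.b2 == pytest.approx(0.001659, abs=5e-6)
        assert bbl.r_squared_pct == pytest.approx(38.7, abs=0.05)
        assert bbl.residual_standard_error == pytest.approx(3.98, abs=5e-3)
        brd = el.fit_quadratic(design, mvc_table, "torso_angle_deg", "BRD")
        assert brd.r_squared_pct == pytest.approx(64.5, abs=0.05)
        assert brd.residual_standard_error == pytest.approx(15.35, abs=5e-3)

    def test_interpolates_level_means(self, design, mvc_table, effects):
        """With 3 equally replicated levels, the parabola passes through the
        level means exactly — the closed-form 3x3 interpolation oracle."""
        fit = el.fit_quadratic(design, mvc_table, "torso_angle_deg", "BBL")
        means = effects.loc["torso_angle_deg", "BBL"]
        levels = means.index.to_numpy(dtype=float)
        V = np.vander(levels, 3, increasing=True)
        coef = np.linalg.solve(V, means.to_numpy())
        assert np.allclose([fit.b0, fit.b1, fit.b2], coef, rtol=1e-9)

    def test_exact_quadratic_has_full_r2_and_zero_residual(self, design):
        x = design["lever_distance_mm"].to_numpy(dtype=float)
        y = 2.0 + 0.3 * x + 0.01 * x**2
        responses = pd.DataFrame({"M": y}, index=design.index)
        fit = el.fit_quadratic(design, responses, "lever_distance_mm", "M")
        assert fit.r_squared_pct == pytest.approx(100.0, abs=1e-8)
        assert fit.residual_standard_error == pytest.approx(0.0, abs=1e-8)

    def test_collinear_levels_rejected(self, mvc_table):
        design = el.datasets.load_design().copy()
        design["torso_angle_deg"] = 0
        with pytest.raises(ValueError, match="distinct levels"):
            el.fit_quadratic(design, mvc_table, "torso_angle_deg", "BBL")


class TestOptima:
    def test_reproduces_printed_optima(self, effects):
        optima = el.optimal_levels(effects)
        printed = el.datasets.load_optima().drop(index="Overall")
        for muscle in printed.index:
            for factor in printed.columns:
                assert optima.loc[muscle, factor] == printed.loc[muscle, factor]

    def test_overall_recommendation(self, effects):
        overall = el.overall_recommendation(el.optimal_levels(effects))
        assert overall["torso_angle_deg"] == 0.0
        assert overall["lever_distance_mm"] == 37.5
        assert overall["lever_orientation_deg"] == 15.0

    def test_all_equal_effects_tie_to_first_level_with_warning(self, design):
        flat = pd.DataFrame(1.0, index=design.index, columns=["M"])
        effects = el.main_effects(design, flat)
        with pytest.warns(UserWarning, match="tie"):
            optima = el.optimal_levels(effects)
        # first level in design order is the factor's level 1
        assert optima.loc["M", "torso_angle_deg"] == 45
        assert optima.loc["M", "lever_distance_mm"] == 0
        assert optima.loc["M", "lever_orientation_deg"] == -30


class TestSurface:
    def test_grid_surface_reproduces_design_points(self, design, mvc_table):
        pair = ("torso_angle_deg", "lever_distance_mm")
        grids = el.interaction_grid(design, mvc_table, pair)
        surfaces = el.design_space_surface(pair, resolution=46, grids=grids)
        for muscle, grid in grids.items():
            for row in grid.index:
                for col in grid.columns:
                    assert surfaces[muscle].at(row, col) == pytest.approx(
                        grid.loc[row, col], rel=1e-9)

    def test_constant_responses_give_flat_surface(self, design):
        flat = pd.DataFrame(4.0, index=design.index, columns=["M"])
        pair = ("torso_angle_deg", "lever_orientation_deg")
        grids = el.interaction_grid(design, flat, pair)
        surfaces = el.design_space_surface(pair, resolution=5, grids=grids)
        assert np.allclose(surfaces["M"].values, 4.0)

    def test_quadratic_surface_finds_injected_minimum(self, design):
        """Responses built with a known minimum at (0 deg, 50 mm) put the
        argmin of the additive-quadratic surface there."""
        lam = design["torso_angle_deg"].to_numpy(dtype=float)
        dist = design["lever_distance_mm"].to_numpy(dtype=float)
        y = 50.0 + 0.02 * lam**2 + 0.004 * (dist - 50.0) ** 2
        responses = pd.DataFrame({"M": y}, index=design.index)
        fits = {"M": (
            el.fit_quadratic(design, responses, "torso_angle_deg", "M"),
            el.fit_quadratic(design, responses, "lever_distance_mm", "M"),
        )}
        surfaces = el.design_space_surface(
            ("torso_angle_deg", "lever_distance_mm"), resolution=46,
            fits=fits, grand_means=responses.mean())
        assert surfaces["M"].argmin == (0.0, 50.0)

    def test_resolution_below_two_rejected(self, design, mvc_table):
        pair = ("torso_angle_deg", "lever_distance_mm")
        grids = el.interaction_grid(design, mvc_table, pair)
        with pytest.raises(ValueError, match="resolution"):
            el.design_space_surface(pair, resolution=1, grids=grids)


def test_effects_report_bundles_consistent_tables(design, mvc_table):
    report = el.effects_report(design, mvc_table)
    assert report.fits.shape[0] == 12  # 3 factors x 4 muscles
    assert set(report.interaction_grids) == {
        ("torso_angle_deg", "lever_distance_mm"),
        ("torso_angle_deg", "lever_orientation_deg"),
        ("lever_distance_mm", "lever_orientation_deg"),
    }
    payload = report.to_dict()
    assert payload["overall_recommendation"]["lever_distance_mm"] == 37.5
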
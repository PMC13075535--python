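"""Taguchi L9 design construction and ergonomic effect analysis.

Three seating factors at three levels each — torso angle λ (0/30/45°, from
vertical in the coronal plane), lever distance L (0/50/100 mm seat-backrest
offset) and lever orientation ψ (−30° pronation / 0 neutral / +30°
supination) — would need 27 full-factorial runs; the L9 orthogonal array is
the standard 1/3 fraction covering every factor-level three times and every
ordered level pair of any two factors exactly once.

On the 9 run responses (the weighted MVC per muscle) the module computes
main effects (level means), 3x3 interaction grids (cell averaging — in an L9
each cell is a single run and two-factor interactions are confounded with
the remaining main effect, so grids are descriptive, not orthogonal
estimates), quadratic response-surface fits per factor, per-muscle minima
and the averaged overall recommendation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "FactorSpec",
    "DEFAULT_FACTORS",
    "QuadraticFit",
    "Surface",
    "EffectsReport",
    "build_l9",
    "main_effects",
    "interaction_grid",
    "fit_quadratic",
    "optimal_levels",
    "overall_recommendation",
    "design_space_surface",
    "effects_report",
]

# Standard L9 orthogonal array, level indices 0..2 per factor.
_L9 = np.array([
    [0, 0, 0], [0, 1, 1], [0, 2, 2],
    [1, 0, 1], [1, 1, 2], [1, 2, 0],
    [2, 0, 2], [2, 1, 0], [2, 2, 1],
])


@dataclass(frozen=True)
class FactorSpec:
    """One ergonomic factor: name, ordered numeric levels, text labels."""

    name: str
    levels: tuple[float, float, float]
    labels: tuple[str, str, str] = ("L1", "L2", "L3")

    def __post_init__(self):
        if len(self.levels) != 3 or len(set(self.levels)) != 3:
            raise ValueError(f"{self.name}: exactly 3 distinct levels required")
        if len(self.labels) != 3:
            raise ValueError(f"{self.name}: exactly 3 labels required")


#: Study factor levels in their design order (level 1, 2, 3).
DEFAULT_FACTORS = (
    FactorSpec("torso_angle_deg", (45.0, 30.0, 0.0),
               ("Highly inclined", "Inclined", "Straight")),
    FactorSpec("lever_distance_mm", (0.0, 50.0, 100.0),
               ("Farthest", "Neutral", "Closest")),
    FactorSpec("lever_orientation_deg", (-30.0, 0.0, 30.0),
               ("Pronation", "Neutral", "Supination")),
)


def build_l9(factors: tuple[FactorSpec, ...] = DEFAULT_FACTORS) -> pd.DataFrame:
    """Assign the standard L9 array to three factors.

    Returns a 9-run design indexed E1-E9 with one numeric column per factor.
    With the default factor/level ordering this reproduces the study's
    design table row for row.
    """
    if len(factors) != 3:
        raise ValueError(f"exactly 3 factors required, got {len(factors)}")
    data = {
        f.name: [f.levels[_L9[run, j]] for run in range(9)]
        for j, f in enumerate(factors)
    }
    design = pd.DataFrame(data, index=[f"E{i + 1}" for i in range(9)])
    design.index.name = "run_id"
    return design


def _check_responses(design: pd.DataFrame, responses: pd.DataFrame) -> pd.DataFrame:
    missing = design.index.difference(responses.index)
    if len(missing):
        raise ValueError(f"responses missing run(s): {missing.tolist()}")
    return responses.loc[design.index]


def _levels_in_design_order(design: pd.DataFrame, factor: str) -> list[float]:
    """Factor levels ordered by first appearance (the design's level order)."""
    return list(dict.fromkeys(design[factor]))


def main_effects(design: pd.DataFrame, responses: pd.DataFrame) -> pd.DataFrame:
    """Mean response per (factor, level), per muscle.

    Rows carry a (factor, level) MultiIndex with levels in design order;
    columns are the response (muscle) columns. In a balanced L9 each level
    mean averages exactly 3 runs, and for every factor the mean of the three
    level means equals the grand mean of all 9 runs.
    """
    responses = _check_responses(design, responses)
    blocks = []
    for factor in design.columns:
        means = responses.groupby(design[factor]).mean()
        means = means.loc[_levels_in_design_order(design, factor)]
        means.index = pd.MultiIndex.from_product(
            [[factor], means.index], names=["factor", "level"])
        blocks.append(means)
    return pd.concat(blocks)


def interaction_grid(
    design: pd.DataFrame, responses: pd.DataFrame,
    factor_pair: tuple[str, str],
) -> dict[str, pd.DataFrame]:
    """Response averaged over the cross of two factors' levels.

    Returns one 3x3 grid per muscle (rows = first factor's levels, columns =
    second factor's, both in design order). In an L9 every cell holds exactly
    one run, so the grid redisplays the runs; its row and column means equal
    the corresponding main effects.
    """
    f1, f2 = factor_pair
    if f1 == f2:
        raise ValueError("factor_pair must name two distinct factors")
    responses = _check_responses(design, responses)
    rows = _levels_in_design_order(design, f1)
    cols = _levels_in_design_order(design, f2)
    grids = {}
    for muscle in responses.columns:
        grid = (
            pd.concat([design[[f1, f2]], responses[muscle]], axis=1)
            .pivot_table(index=f1, columns=f2, values=muscle, aggfunc="mean")
            .loc[rows, cols]
        )
        grids[muscle] = grid
    return grids


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit of 9 run responses on (1, x, x^2) of one factor's levels.

    With 3 distinct levels replicated 3 times each, the fitted parabola
    interpolates the three level means exactly, so b0 equals the mean at
    x=0 whenever 0 is a level. r_squared_pct is the between-level share of
    total variation (x100); residual_standard_error is sqrt(SSE / 6), the
    9-run fit having 6 residual degrees of freedom.
    """

    factor: str
    muscle: str
    b0: float
    b1: float
    b2: float
    r_squared_pct: float
    residual_standard_error: float
    sse: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x**2


def fit_quadratic(
    design: pd.DataFrame, responses: pd.DataFrame,
    factor: str, muscle: str,
) -> QuadraticFit:
    """Quadratic response curve for one factor-muscle relationship."""
    responses = _check_responses(design, responses)
    x = design[factor].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(f"{factor}: need 3 distinct levels for a quadratic fit")
    y = responses[muscle].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([x, x**2]))
    fit = sm.OLS(y, X).fit()
    return QuadraticFit(
        factor=factor,
        muscle=muscle,
        b0=float(fit.params[0]),
        b1=float(fit.params[1]),
        b2=float(fit.params[2]),
        r_squared_pct=float(fit.rsquared * 100.0),
        residual_standard_error=float(np.sqrt(fit.ssr / fit.df_resid)),
        sse=float(fit.ssr),
    )


def optimal_levels(effects: pd.DataFrame) -> pd.DataFrame:
    """Per muscle and factor, the level with the smallest mean response.

    Minimum effort is the ergonomic objective. Ties go to the earlier level
    in design order, with a warning (the study data contain none).
    """
    muscles = effects.columns
    factors = effects.index.get_level_values("factor").unique()
    out = pd.DataFrame(index=muscles, columns=factors, dtype=float)
    out.index.name = "muscle"
    for factor in factors:
        block = effects.loc[factor]
        for muscle in muscles:
            col = block[muscle]
            if (col == col.min()).sum() > 1:
                warnings.warn(
                    f"tie for minimum at factor {factor!r}, muscle {muscle!r}; "
                    "choosing the earlier level",
                    stacklevel=2,
                )
            out.loc[muscle, factor] = col.idxmin()
    return out


def overall_recommendation(optima: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the muscles' optimal numeric settings per factor —
    the generalized single-setting recommendation."""
    rec = optima.mean(axis=0)
    rec.name = "optimal_setting"
    return rec


@dataclass(frozen=True)
class Surface:
    """Gridded response surface over two factors' numeric ranges."""

    factor_x: str
    factor_y: str
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # shape (len(x), len(y))
    argmin: tuple[float, float]
    argmax: tuple[float, float]

    def at(self, xv: float, yv: float) -> float:
        i = int(np.argmin(np.abs(self.x - xv)))
        j = int(np.argmin(np.abs(self.y - yv)))
        return float(self.values[i, j])


def design_space_surface(
    factor_pair: tuple[str, str],
    resolution: int = 21,
    grids: dict[str, pd.DataFrame] | None = None,
    fits: dict[str, tuple[QuadraticFit, QuadraticFit]] | None = None,
    grand_means: pd.Series | None = None,
) -> dict[str, Surface]:
    """Evaluate the two-factor design space on a rectangular grid.

    Two constructions, per muscle:

    * from ``grids`` — bilinear interpolation of the 3x3 interaction grid;
      reproduces the grid cells exactly at the design points.
    * from ``fits`` — the additive quadratic surface q_x(x) + q_y(y) − grand
      mean, combining the two single-factor response curves.

    Returns one :class:`Surface` per muscle with argmin/argmax grid cells
    (the low- and high-strain corners of the design space).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if (grids is None) == (fits is None):
        raise ValueError("provide exactly one of grids= or fits=")
    fx, fy = factor_pair

    surfaces = {}
    if grids is not None:
        for muscle, grid in grids.items():
            rows = np.array(sorted(grid.index), dtype=float)
            cols = np.array(sorted(grid.columns), dtype=float)
            z = grid.loc[rows, cols].to_numpy(dtype=float)
            interp = RegularGridInterpolator((rows, cols), z)
            xs = _axis(rows[0], rows[-1], resolution, rows)
            ys = _axis(cols[0], cols[-1], resolution, cols)
            xx, yy = np.meshgrid(xs, ys, indexing="ij")
            vals = interp(np.column_stack([xx.ravel(), yy.ravel()]))
            surfaces[muscle] = _make_surface(fx, fy, xs, ys,
                                             vals.reshape(xx.shape))
    else:
        if grand_means is None:
            raise ValueError("grand_means is required with fits=")
        for muscle, (qx, qy) in fits.items():
            if (qx.factor, qy.factor) != (fx, fy):
                raise ValueError(
                    f"fits for {muscle} are ({qx.factor}, {qy.factor}), "
                    f"expected {factor_pair}")
            levels_x, levels_y = _factor_levels(fx), _factor_levels(fy)
            xs = _axis(min(levels_x), max(levels_x), resolution, levels_x)
            ys = _axis(min(levels_y), max(levels_y), resolution, levels_y)
            vals = (qx.predict(xs)[:, None] + qy.predict(ys)[None, :]
                    - float(grand_means[muscle]))
            surfaces[muscle] = _make_surface(fx, fy, xs, ys, vals)
    return surfaces


def _axis(lo: float, hi: float, resolution: int, knots) -> np.ndarray:
    """Evaluation axis: uniform grid plus the design-level knots, so the
    surface is exact at every design point regardless of resolution."""
    return np.unique(np.concatenate([
        np.linspace(lo, hi, resolution), np.asarray(knots, dtype=float)]))


def _factor_levels(name: str) -> np.ndarray:
    for f in DEFAULT_FACTORS:
        if f.name == name:
            return np.asarray(f.levels, dtype=float)
    raise ValueError(f"unknown factor {name!r}; pass grids= for custom factors")


def _make_surface(fx, fy, xs, ys, vals) -> Surface:
    imin = np.unravel_index(np.argmin(vals), vals.shape)
    imax = np.unravel_index(np.argmax(vals), vals.shape)
    return Surface(fx, fy, xs, ys, vals,
                   argmin=(float(xs[imin[0]]), float(ys[imin[1]])),
                   argmax=(float(xs[imax[0]]), float(ys[imax[1]])))


@dataclass
class EffectsReport:
    """Complete design-analysis bundle for one response table."""

    design: pd.DataFrame
    responses: pd.DataFrame
    main_effects: pd.DataFrame
    interaction_grids: dict[tuple[str, str], dict[str, pd.DataFrame]]
    fits: pd.DataFrame
    optima: pd.DataFrame
    overall: pd.Series
    grand_means: pd.Series = field(default=None)

    def to_dict(self) -> dict:
        """JSON-serialisable view of every table."""
        me = self.main_effects.reset_index()
        return {
            "design": self.design.reset_index().to_dict(orient="records"),
            "main_effects": me.to_dict(orient="records"),
            "interaction_grids": {
                "x".join(pair): {
                    muscle: {
                        "rows": list(map(float, g.index)),
                        "cols": list(map(float, g.columns)),
                        "values": g.to_numpy().tolist(),
                    }
                    for muscle, g in grids.items()
                }
                for pair, grids in self.interaction_grids.items()
            },
            "quadratic_fits": self.fits.reset_index().to_dict(orient="records"),
            "optima": self.optima.reset_index().to_dict(orient="records"),
            "overall_recommendation": {k: float(v) for k, v in self.overall.items()},
            "grand_means": {k: float(v) for k, v in self.grand_means.items()},
        }


def effects_report(design: pd.DataFrame, responses: pd.DataFrame) -> EffectsReport:
    """Run the full effect analysis on a 9-run response table."""
    responses = _check_responses(design, responses)
    effects = main_effects(design, responses)
    pairs = [(a, b) for i, a in enumerate(design.columns)
             for b in design.columns[i + 1:]]
    grids = {pair: interaction_grid(design, responses, pair) for pair in pairs}
    fit_rows = []
    for factor in design.columns:
        for muscle in responses.columns:
            q = fit_quadratic(design, responses, factor, muscle)
            fit_rows.append({
                "factor": factor, "muscle": muscle,
                "b0": q.b0, "b1": q.b1, "b2": q.b2,
                "r_squared_pct": q.r_squared_pct,
                "residual_standard_error": q.residual_standard_error,
                "sse": q.sse,
            })
    fits = pd.DataFrame(fit_rows).set_index(["factor", "muscle"])
    optima = optimal_levels(effects)
    return EffectsReport(
        design=design,
        responses=responses,
        main_effects=effects,
        interaction_grids=grids,
        fits=fits,
        optima=optima,
        overall=overall_recommendation(optima),
        grand_means=responses.mean(),
    )
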
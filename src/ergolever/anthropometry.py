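"""Anthropometric summaries, reach-envelope checks and turning geometry.

The wheelchair's seating and reach dimensions are driven by a seated
anthropometric survey (5th/95th percentile design bounds) and four
closed-form reach constraints from a digital human model, all in mm:

* forward high:  H1 + E·cos λ + K·sin 45° ≥ 1200
* forward low:   H1 + E·cos λ − K·sin 45° ≥ 400
* lateral high:  H1 + E       + K·sin 45° ≥ 1300
* lateral low:   H1 + E·sin τ − K·sin 45° ≥ 250

where H1 is ground-to-seat height (500 mm default), E the seated shoulder
height, K the shoulder-grip length, λ the torso angle with the coronal
plane and τ the torso angle with the sagittal plane. The 360° turning
clearance follows from the footprint half-lengths L1/2 and L2/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WheelchairGeometry",
    "percentile_summary",
    "reach_check",
    "turning_distance",
    "clearance_report",
]

_SIN45 = np.sin(np.pi / 4)

#: Reach bound (mm) per constraint, and the sense of each comparison.
REACH_BOUNDS_MM = {
    "forward_high": 1200.0,
    "forward_low": 400.0,
    "lateral_high": 1300.0,
    "lateral_low": 250.0,
}


@dataclass(frozen=True)
class WheelchairGeometry:
    """Prototype geometry, mm and degrees.

    torso_sagittal_angle_deg (τ) enters only the lateral-low constraint and
    has no single published value; the upright default 0° makes that
    constraint maximally conservative (sin τ = 0 drops the shoulder term).
    """

    seat_height_mm: float = 500.0       # H1, ground to lowest seat point
    length_mm: float = 600.0            # L1, footprint length parameter
    width_mm: float = 950.0             # L2, footprint width parameter
    torso_coronal_angle_deg: float = 0.0    # λ
    torso_sagittal_angle_deg: float = 0.0   # τ

    def __post_init__(self):
        for name in ("seat_height_mm", "length_mm", "width_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("torso_coronal_angle_deg", "torso_sagittal_angle_deg"):
            if not 0 <= getattr(self, name) <= 90:
                raise ValueError(f"{name} must lie in [0, 90] degrees")


def percentile_summary(
    table: pd.DataFrame, percentiles: tuple[float, ...] = (5, 95),
) -> pd.DataFrame:
    """Per-feature mean, SD and empirical percentile bounds.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default), pinned here for cross-implementation reproducibility.
    SD is the sample (n−1) convention.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    out = pd.DataFrame({
        "mean": table.mean(),
        "sd": table.std(ddof=1),
    })
    for p in percentiles:
        out[f"p{p:g}"] = table.quantile(p / 100.0, interpolation="linear")
    out.index.name = "feature"
    return out


def reach_check(
    geometry: WheelchairGeometry, shoulder_height_mm: float,
    shoulder_grip_mm: float,
) -> pd.DataFrame:
    """Evaluate the four reach constraints for one user.

    ``shoulder_height_mm`` (E) and ``shoulder_grip_mm`` (K) are seated
    dimensions in mm. Returns one row per constraint with the left-hand
    side, bound, margin (LHS − bound) and pass flag.
    """
    if shoulder_height_mm <= 0 or shoulder_grip_mm <= 0:
        raise ValueError("shoulder height E and grip length K must be positive")
    h1 = geometry.seat_height_mm
    e, k = shoulder_height_mm, shoulder_grip_mm
    lam = np.deg2rad(geometry.torso_coronal_angle_deg)
    tau = np.deg2rad(geometry.torso_sagittal_angle_deg)
    lhs = {
        "forward_high": h1 + e * np.cos(lam) + k * _SIN45,
        "forward_low": h1 + e * np.cos(lam) - k * _SIN45,
        "lateral_high": h1 + e + k * _SIN45,
        "lateral_low": h1 + e * np.sin(tau) - k * _SIN45,
    }
    rows = []
    for name, bound in REACH_BOUNDS_MM.items():
        value = float(lhs[name])
        rows.append({
            "constraint": name,
            "lhs_mm": value,
            "bound_mm": bound,
            "margin_mm": value - bound,
            "passed": value >= bound,
        })
    return pd.DataFrame(rows).set_index("constraint")


def turning_distance(
    geometry: WheelchairGeometry,
    interpretation: str = "mean_half_lengths",
) -> float:
    """Minimum travel (mm) for a 360° turn of the footprint.

    ``mean_half_lengths`` (default) treats the turning radius as the mean of
    the footprint half-lengths, 2π·(L1/2 + L2/2) — the reading that matches
    the prototype's stated 4870 mm. ``root_sum_squares`` instead uses the
    diagonal radius, 2π·√(L1² + L2²); it is provided for comparison and is
    inconsistent with that figure (≈7060 mm).
    """
    l1, l2 = geometry.length_mm, geometry.width_mm
    if interpretation == "mean_half_lengths":
        return float(2 * np.pi * (l1 + l2) / 2)
    if interpretation == "root_sum_squares":
        return float(2 * np.pi * np.hypot(l1, l2))
    raise ValueError(
        f"unknown interpretation {interpretation!r}; use "
        "'mean_half_lengths' or 'root_sum_squares'")


def _bound_range(entry) -> tuple[float, float] | None:
    if entry is None:
        return None
    if isinstance(entry, (list, tuple)):
        return float(entry[0]), float(entry[1])
    return float(entry), float(entry)


def clearance_report(
    geometry: WheelchairGeometry,
    standards: dict,
    shoulder_height_mm: float,
    shoulder_grip_mm: float,
) -> pd.DataFrame:
    """Compare computed reach and turning values against each standard.

    Reach rows compare the constraint LHS against each source's lower bound
    ('ge' sense); the manoeuvring row compares the 360° turning distance
    against the source's largest allowed envelope ('le' sense — the
    prototype's large footprint exceeds every published turning envelope).
    Sources with no specified bound are skipped, not failed.
    """
    reach = reach_check(geometry, shoulder_height_mm, shoulder_grip_mm)
    turn = turning_distance(geometry)
    rows = []
    for section, requirements in standards.items():
        for requirement, entry in requirements.items():
            direction = entry.get("direction", "ge")
            if section == "reach":
                if requirement not in reach.index:
                    continue  # obstructed-reach rows have no closed form here
                computed = float(reach.loc[requirement, "lhs_mm"])
            else:
                computed = turn
            for source, bound in entry.items():
                if source == "direction":
                    continue
                rng = _bound_range(bound)
                if rng is None:
                    continue
                lo, hi = rng
                compliant = computed >= lo if direction == "ge" else computed <= hi
                rows.append({
                    "requirement": requirement,
                    "source": source,
                    "bound_low_mm": lo,
                    "bound_high_mm": hi,
                    "computed_mm": computed,
                    "direction": direction,
                    "compliant": compliant,
                })
    return pd.DataFrame(
        rows, columns=["requirement", "source", "bound_low_mm",
                       "bound_high_mm", "computed_mm", "direction", "compliant"])
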
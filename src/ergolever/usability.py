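"""Flat-surface course usability summaries.

The simulated urban course has 9 tasks (concrete stretch, 5° ramp, 90° turn,
floor surfaces, carpets, narrow passage, gradual turn) timed per participant,
plus 4-category Likert favourability ratings per task and 0-10 visual-analog
ratings of overall attributes (comfort, stability, driving control,
perception, maneuverability).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "LIKERT_SCORES",
    "task_time_summary",
    "likert_encode",
    "vas_summary",
]

#: The study's 4-category favourability vocabulary and integer scores.
LIKERT_SCORES = {
    "strongly favorable": 4,
    "moderately favorable": 3,
    "moderately unfavorable": 2,
    "strongly unfavorable": 1,
}


def task_time_summary(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-task mean, sample SD (n−1) and standard error of completion time.

    ``table`` is tasks x participants, seconds. Reported columns are rounded
    half-up to ``decimals`` places (matching how times are quoted); exact
    values are kept in ``*_exact`` columns.
    """
    if table.isna().any().any():
        task, participant = next(
            (t, p) for t in table.index for p in table.columns
            if pd.isna(table.loc[t, p]))
        raise ValueError(f"missing time for task {task!r}, participant {participant!r}")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 participants per task")
    n = table.shape[1]
    mean = table.mean(axis=1)
    sd = table.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    out = pd.DataFrame({
        "mean_exact": mean, "sd_exact": sd, "se_exact": se,
        "mean_s": _round_half_up(mean, decimals),
        "sd_s": _round_half_up(sd, decimals),
        "se_s": _round_half_up(se, decimals),
        "n": n,
    })
    out.index.name = "task"
    return out


def _round_half_up(x: pd.Series, decimals: int) -> pd.Series:
    scale = 10.0 ** decimals
    return np.floor(x * scale + 0.5) / scale


def likert_encode(descriptor: str) -> int:
    """Map a favourability descriptor to its 1-4 score (case-insensitive)."""
    key = " ".join(descriptor.strip().lower().split())
    try:
        return LIKERT_SCORES[key]
    except KeyError:
        raise ValueError(
            f"unknown descriptor {descriptor!r}; valid categories: "
            f"{sorted(LIKERT_SCORES)}") from None


def vas_summary(ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD per attribute of 0-10 visual-analog ratings.

    ``ratings`` is participants x attributes. The lowest- and highest-rated
    attributes are flagged — in a usability readout these are the first
    candidates for redesign and the design's strongest suit respectively.
    """
    values = ratings.to_numpy(dtype=float)
    if ((values < 0) | (values > 10)).any():
        raise ValueError("VAS ratings must lie in [0, 10]")
    out = pd.DataFrame({
        "mean": ratings.mean(),
        "sd": ratings.std(ddof=1),
    })
    out.index.name = "attribute"
    out["lowest"] = out.index == out["mean"].idxmin()
    out["highest"] = out.index == out["mean"].idxmax()
    return out
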
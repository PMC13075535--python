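"""Packaged study tables for the stair-climbing wheelchair assessment.

The fixtures mirror the study's printed tables: anthropometric summaries of
the 20-participant survey, clearance standards, the L9 experimental design,
flat-course task times, per-run sEMG features (amplitude, RMS, weighted MVC)
and the derived main-effect table. They let every analysis stage be exercised
without raw recordings.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

#: Muscle channel labels in recording order: biceps brachii long head,
#: triceps brachii long head, brachioradialis, posterior deltoid.
MUSCLES = ("BBL", "TBL", "BRD", "PDT")

#: Ergonomic factor column names used throughout the design analysis.
FACTORS = ("torso_angle_deg", "lever_distance_mm", "lever_orientation_deg")


def _path(name: str):
    return resources.files("ergolever.data").joinpath(name)


def load_anthropometrics() -> pd.DataFrame:
    """Anthropometric survey summary (means, SDs and printed percentile
    bounds, cm unless suffixed otherwise), indexed by feature."""
    with resources.as_file(_path("table1_anthropometrics.csv")) as p:
        df = pd.read_csv(p, dtype={"annotation": "string"})
    return df.set_index("feature")


def load_clearance_standards() -> dict:
    """Reach/manoeuvring clearance bounds (mm) per standard source."""
    with resources.as_file(_path("table2_clearance_standards.json")) as p:
        standards = json.loads(p.read_text(encoding="utf-8"))
    standards.pop("comment", None)
    return standards


def load_design() -> pd.DataFrame:
    """The 9-run L9 design: factor levels per experiment, indexed E1-E9."""
    with resources.as_file(_path("table5_design.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("run_id")


def load_task_times() -> pd.DataFrame:
    """Flat-course task completion times (s), tasks x participants."""
    with resources.as_file(_path("table6_task_times.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("task")


def load_emg_features() -> pd.DataFrame:
    """Per-run, per-muscle sEMG features: envelope amplitude range,
    RMS and the printed weighted MVC statistic (long format)."""
    with resources.as_file(_path("table7_emg_features.csv")) as p:
        return pd.read_csv(p)


def load_main_effects() -> pd.DataFrame:
    """Printed main-effect means, long format (factor, level, muscle)."""
    with resources.as_file(_path("table9_main_effects.csv")) as p:
        return pd.read_csv(p)


def load_optima() -> pd.DataFrame:
    """Printed optimal settings per muscle plus the 'Overall' averaged row."""
    with resources.as_file(_path("table10_optima.csv")) as p:
        return pd.read_csv(p).set_index("muscle")


def mvc_wide(features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot the long feature table to a run x muscle MVC matrix."""
    if features is None:
        features = load_emg_features()
    wide = features.pivot(index="run_id", columns="muscle", values="mvc")
    return wide.loc[sorted(wide.index), list(MUSCLES)]
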
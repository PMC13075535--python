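"""Weighted MVC statistic and muscle-coordination correlation.

The study's "MVC" is a per-task weighted statistic on the filtered EMG
series X: MVC = w1*A + w2*RMS, with A = max(X) - min(X) the envelope
amplitude range and RMS the root mean square, weighted w1=0.7 / w2=0.3 to
prioritise sensitivity to full recruitment peaks while RMS tempers outliers.
It is NOT a normalised %MVC against a reference maximal contraction — no
calibration contractions exist; the field name is kept for continuity with
the source tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EMGFeatures",
    "features",
    "mvc",
    "mvc_from_series",
    "coordination_matrix",
    "W1_DEFAULT",
    "W2_DEFAULT",
]

W1_DEFAULT = 0.7  # weight on amplitude range A
W2_DEFAULT = 0.3  # weight on RMS


@dataclass(frozen=True)
class EMGFeatures:
    """Scalar features of one processed channel series."""

    amplitude: float
    rms: float
    channel: str = ""
    run_id: str = ""

    def __post_init__(self):
        if self.amplitude < 0 or self.rms < 0:
            raise ValueError("amplitude and rms must be non-negative")


def features(series: np.ndarray, channel: str = "", run_id: str = "") -> EMGFeatures:
    """Amplitude range A = max - min and RMS of a series."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("series is empty")
    return EMGFeatures(
        amplitude=float(x.max() - x.min()),
        rms=float(np.sqrt(np.mean(np.square(x)))),
        channel=channel,
        run_id=run_id,
    )


def mvc(feats: EMGFeatures, w1: float = W1_DEFAULT, w2: float = W2_DEFAULT) -> float:
    """Weighted MVC statistic w1*A + w2*RMS."""
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")
    return w1 * feats.amplitude + w2 * feats.rms


def mvc_from_series(series: np.ndarray, w1: float = W1_DEFAULT,
                    w2: float = W2_DEFAULT) -> float:
    """Convenience: features + weighting in one call."""
    return mvc(features(series), w1=w1, w2=w2)


def coordination_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between muscles' MVC values across runs.

    ``table`` is runs x muscles. A muscle with zero variance across runs has
    no defined correlation; its pairs are reported as NaN with a warning
    rather than silently zeroed. Needs at least 3 runs for the coefficient
    to be meaningful.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 runs to correlate")
    constant = table.columns[table.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant MVC column(s) {constant}: correlations undefined (NaN)",
            stacklevel=2,
        )
    values = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    out = pd.DataFrame(r, index=table.columns, columns=table.columns)
    np.fill_diagonal(out.values, 1.0)
    for col in constant:
        out.loc[col, :] = np.nan
        out.loc[:, col] = np.nan
        out.loc[col, col] = np.nan
    return out
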
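"""Seeded synthetic data with the statistical structure the analysis assumes.

Emulates what the hardware study measured, without hardware: multi-channel
sEMG recordings structured as repeated pull-push lever cycles (elbow flexors
and the posterior deltoid burst while pulling, the triceps while pushing),
anthropometric samples drawn from survey summary statistics, and task-time /
rating tables. Burst carriers are band-limited Gaussian noise — adequate for
testing envelope, detection and DOE stages; no motor-unit action-potential
shapes or electrode-skin effects are modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, sosfiltfilt

from .signal_processing import RawEMGRecording

__all__ = [
    "BurstSchedule",
    "SignalModel",
    "GroundTruth",
    "generate_recording",
    "generate_anthropometrics",
    "generate_run_suite",
    "generate_task_times",
    "generate_vas_ratings",
    "DEFAULT_PHASES",
]

#: Which propulsion phase each muscle bursts in: pulling engages the elbow
#: flexors (BBL, BRD) and shoulder extensor (PDT); pushing engages the
#: elbow extensor (TBL).
DEFAULT_PHASES: dict[str, str] = {
    "BBL": "pull", "BRD": "pull", "PDT": "pull", "TBL": "push",
}


@dataclass(frozen=True)
class BurstSchedule:
    """Timing template of the repeated pull-push-rest lever cycle.

    Defaults (1.0 s pull, 1.0 s push, 0.5 s rest) are a desk-scale cadence
    choice; the study reports no cycle timing.
    """

    cycle_count: int = 5
    pull_duration: float = 1.0
    push_duration: float = 1.0
    rest_duration: float = 0.5
    phase_assignment: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PHASES))

    def __post_init__(self):
        if self.cycle_count < 1:
            raise ValueError("cycle_count must be >= 1")
        for name in ("pull_duration", "push_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.phase_assignment.values()) - {"pull", "push"}
        if bad:
            raise ValueError(
                f"phase_assignment values must be 'pull' or 'push', got {bad}")

    @property
    def cycle_duration(self) -> float:
        return self.pull_duration + self.push_duration + self.rest_duration


@dataclass(frozen=True)
class SignalModel:
    """Stochastic model of one multi-channel recording.

    Bursts are Gaussian noise band-passed to ``burst_band`` (spectral support
    of surface EMG below the 250 Hz Nyquist of the 500 Hz system), scaled to
    ``burst_amplitude`` (arbitrary units, matching the unitless printed
    feature tables) and superposed on baseline Gaussian noise.
    """

    sampling_rate: float = 500.0
    burst_band: tuple[float, float] = (20.0, 200.0)
    burst_amplitude: dict[str, float] = field(
        default_factory=lambda: {ch: 10.0 for ch in DEFAULT_PHASES})
    baseline_noise_sd: float = 1.0
    seed: int = 0
    edge_taper_s: float = 0.025  # linear onset/offset ramp, avoids splatter

    def __post_init__(self):
        low, high = self.burst_band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError(
                f"burst_band must satisfy 0 < low < high < Nyquist "
                f"({self.sampling_rate / 2} Hz), got {self.burst_band}")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")
        for ch, amp in self.burst_amplitude.items():
            if amp <= self.baseline_noise_sd:
                raise ValueError(
                    f"burst_amplitude[{ch!r}]={amp} must exceed "
                    f"baseline_noise_sd={self.baseline_noise_sd}")


@dataclass(frozen=True)
class GroundTruth:
    """True burst intervals (half-open sample index pairs) per channel,
    plus the generating amplitude, for detector scoring."""

    intervals: dict[str, list[tuple[int, int]]]
    amplitudes: dict[str, float]

    def __post_init__(self):
        for ch, ivals in self.intervals.items():
            prev_end = -1
            for onset, offset in ivals:
                if onset <= prev_end or offset <= onset:
                    raise ValueError(
                        f"intervals for {ch} must be strictly increasing "
                        "and non-overlapping")
                prev_end = offset

    def to_json(self, path) -> None:
        payload = {ch: [list(iv) for iv in ivals]
                   for ch, ivals in self.intervals.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _band_limited_burst(rng: np.random.Generator, n: int, band, fs: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to the EMG carrier band."""
    # generous padding so filter transients never touch the burst
    pad = int(fs)
    white = rng.standard_normal(n + 2 * pad)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sosfiltfilt(sos, white)[pad:pad + n]
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_recording(
    schedule: BurstSchedule, model: SignalModel,
) -> tuple[RawEMGRecording, GroundTruth]:
    """Synthesize one multi-channel recording plus its ground truth.

    Each channel carries baseline Gaussian noise everywhere and, inside its
    phase's windows, an added band-limited burst scaled to the channel
    amplitude with a linear edge taper. Identical inputs (including
    ``model.seed``) give bit-identical output.
    """
    fs = model.sampling_rate
    n_total = round(schedule.cycle_count * schedule.cycle_duration * fs)
    rng = np.random.default_rng(model.seed)

    pull_n = round(schedule.pull_duration * fs)
    push_n = round(schedule.push_duration * fs)
    cycle_n = round(schedule.cycle_duration * fs)
    windows = {"pull": [], "push": []}
    for c in range(schedule.cycle_count):
        start = c * cycle_n
        windows["pull"].append((start, min(start + pull_n, n_total)))
        windows["push"].append((start + pull_n,
                                min(start + pull_n + push_n, n_total)))

    taper_n = round(model.edge_taper_s * fs)
    labels = tuple(schedule.phase_assignment)
    samples = np.empty((n_total, len(labels)))
    truth_intervals: dict[str, list[tuple[int, int]]] = {}
    for j, ch in enumerate(labels):
        x = rng.normal(0.0, model.baseline_noise_sd, n_total) \
            if model.baseline_noise_sd > 0 else np.zeros(n_total)
        amp = model.burst_amplitude.get(ch)
        if amp is None:
            raise ValueError(f"burst_amplitude missing channel {ch!r}")
        ivals = windows[schedule.phase_assignment[ch]]
        for onset, offset in ivals:
            m = offset - onset
            burst = amp * _band_limited_burst(rng, m, model.burst_band, fs)
            if taper_n > 0 and m > 2 * taper_n:
                ramp = np.linspace(0.0, 1.0, taper_n)
                burst[:taper_n] *= ramp
                burst[-taper_n:] *= ramp[::-1]
            x[onset:offset] += burst
        samples[:, j] = x
        truth_intervals[ch] = list(ivals)

    recording = RawEMGRecording(samples, fs, labels)
    truth = GroundTruth(truth_intervals, dict(model.burst_amplitude))
    return recording, truth


def generate_anthropometrics(
    n: int, summary: pd.DataFrame, seed: int = 0,
) -> pd.DataFrame:
    """Draw an anthropometric sample table from per-feature summaries.

    ``summary`` needs ``mean`` and ``sd`` columns indexed by feature (the
    packaged survey table works directly). Each feature is drawn from a
    normal distribution truncated at mean +/- 4 SD; an SD of zero yields the
    mean exactly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if (summary["sd"] < 0).any():
        bad = summary.index[summary["sd"] < 0].tolist()
        raise ValueError(f"negative sd for feature(s): {bad}")
    rng = np.random.default_rng(seed)
    out = {}
    for feature, row in summary.iterrows():
        mean, sd = float(row["mean"]), float(row["sd"])
        if sd == 0:
            out[feature] = np.full(n, mean)
        else:
            out[feature] = stats.truncnorm.rvs(
                -4, 4, loc=mean, scale=sd, size=n, random_state=rng)
    table = pd.DataFrame(out)
    table.index = [f"P{i + 1}" for i in range(n)]
    table.index.name = "subject"
    return table


def generate_run_suite(
    design: pd.DataFrame,
    effect_model: dict[str, dict[float, float]] | None = None,
    base_model: SignalModel | None = None,
    schedule: BurstSchedule | None = None,
    seed: int | None = None,
) -> dict[str, tuple[RawEMGRecording, GroundTruth]]:
    """One recording per design run, with amplitudes shaped by factor levels.

    ``effect_model`` maps factor name -> {level: amplitude multiplier}; each
    run's channel amplitudes are the base amplitudes times the product of its
    levels' multipliers (missing entries default to 1). This injects a known
    monotone effect structure so the downstream design analysis can be tested
    for parameter recovery.
    """
    if design.shape[0] != 9:
        raise ValueError(f"design must have 9 runs, got {design.shape[0]}")
    effect_model = effect_model or {}
    base_model = base_model or SignalModel()
    schedule = schedule or BurstSchedule()
    if seed is None:
        seed = base_model.seed
    run_seeds = np.random.SeedSequence(seed).generate_state(design.shape[0])

    suite = {}
    for run_seed, (run_id, row) in zip(run_seeds, design.iterrows()):
        multiplier = 1.0
        for factor in design.columns:
            if factor not in row:
                raise ValueError(f"run {run_id} missing factor {factor}")
            multiplier *= effect_model.get(factor, {}).get(float(row[factor]), 1.0)
        amplitudes = {ch: amp * multiplier
                      for ch, amp in base_model.burst_amplitude.items()}
        model = replace(base_model, burst_amplitude=amplitudes,
                        seed=int(run_seed % 2**31))
        suite[run_id] = generate_recording(schedule, model)
    return suite


def generate_task_times(
    summary: pd.DataFrame, n_participants: int = 9, seed: int = 0,
) -> pd.DataFrame:
    """Task x participant completion times (s) from per-task mean/sd,
    truncated below at 0.5 s so times stay physically positive."""
    rng = np.random.default_rng(seed)
    rows = {}
    for task, row in summary.iterrows():
        mean, sd = float(row["mean"]), float(row["sd"])
        draws = rng.normal(mean, sd, n_participants) if sd > 0 \
            else np.full(n_participants, mean)
        rows[task] = np.clip(draws, 0.5, None)
    table = pd.DataFrame(rows).T
    table.columns = [f"S{i + 1}" for i in range(n_participants)]
    table.index.name = "task"
    return table


def generate_vas_ratings(
    summary: pd.DataFrame, n_participants: int = 9, seed: int = 0,
) -> pd.DataFrame:
    """Participant x attribute 0-10 visual-analog ratings from per-attribute
    mean/sd summaries, clipped to the scale."""
    rng = np.random.default_rng(seed)
    cols = {}
    for attribute, row in summary.iterrows():
        draws = rng.normal(float(row["mean"]), float(row["sd"]), n_participants)
        cols[attribute] = np.clip(draws, 0.0, 10.0)
    table = pd.DataFrame(cols)
    table.index = [f"S{i + 1}" for i in range(n_participants)]
    table.index.name = "participant"
    return table
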
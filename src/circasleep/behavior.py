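"""Barnes-maze spatial-learning metrics from scored trial tables.

The module consumes already-scored trial tables (video tracking is out of
scope): one row per animal/day/trial with primary latency (time to first
investigate the escape hole, capped at 180 s), primary errors (incorrect
holes investigated before it), time in the open centre of the table (an
inverse anxiety measure) and freezing time.

Learning over the 5 training days is summarized as the trapezoidal area
under the per-day mean curve (AUC) over the day index (unit spacing); a
lower AUC means faster learning.  The day-1 point serves as the baseline
and is included by default.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError

TRIAL_CAP_S = 180.0
PROBE_CAP_S = 60.0
MEASURES = ("primary_latency_s", "primary_errors", "time_in_center_s",
            "freezing_s")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"animal_id", "day", "trial", "primary_latency_s",
                "primary_errors"}
    missing = required - set(trials.columns)
    if missing:
        raise ConfigurationError(f"trial table missing columns {sorted(missing)}")
    lat = trials["primary_latency_s"]
    cap = np.where(trials["day"] > 5, PROBE_CAP_S, TRIAL_CAP_S)
    if ((lat <= 0) | (lat > cap)).any():
        raise ConfigurationError(
            "primary latency outside (0, cap] for some trials")
    return trials


def daily_means(trials: pd.DataFrame,
                expected_trials: int = 2) -> pd.DataFrame:
    """Per animal/day arithmetic mean of each scored measure.

    Days with fewer than ``expected_trials`` trials are flagged (training
    days have two trials; the probe day has one).
    """
    trials = validate_trials(trials)
    measures = [m for m in MEASURES if m in trials.columns]
    grouped = trials.groupby(["animal_id", "day"])
    out = grouped[measures].mean().reset_index()
    n = grouped.size()
    short = n[(n < expected_trials) & (n.index.get_level_values("day") <= 5)]
    if len(short):
        warnings.warn(f"{len(short)} animal-days have missing trials")
    return out


def learning_auc(series: pd.Series) -> float:
    """Trapezoidal AUC of a day-indexed series over the day index.

    Requires >= 2 days.  A missing interior day is linearly interpolated
    (which the trapezoid over actual day values performs implicitly) and
    flagged.
    """
    s = series.dropna().sort_index()
    if len(s) < 2:
        raise ConfigurationError("learning AUC requires >= 2 days")
    days = s.index.to_numpy(dtype=float)
    if np.any(np.diff(days) > 1):
        warnings.warn("missing interior day(s): linear interpolation applied")
    return float(np.trapezoid(s.to_numpy(dtype=float), days))


def learning_auc_table(daily: pd.DataFrame,
                       measure: str = "primary_latency_s",
                       max_day: int = 5) -> pd.Series:
    """Per-animal learning AUC over the training days (probe day excluded)."""
    sub = daily[daily["day"] <= max_day]
    return (sub.set_index("day")
               .groupby("animal_id")[measure]
               .apply(learning_auc)
               .rename(f"{measure}_auc"))


def behavior_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-animal table: latency/error AUCs plus mean centre and freezing time."""
    daily = daily_means(trials)
    out = learning_auc_table(daily, "primary_latency_s").to_frame()
    out["primary_errors_auc"] = learning_auc_table(daily, "primary_errors")
    train = daily[daily["day"] <= 5]
    for m in ("time_in_center_s", "freezing_s"):
        if m in daily.columns:
            out[f"{m}_mean"] = train.groupby("animal_id")[m].mean()
    return out.reset_index()
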
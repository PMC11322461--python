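"""Sleep-architecture metrics derived from the hypnogram alone.

Metrics are binned on the ZT axis (3, 12 or 24 h bins, labeled with the
bin's initial ZT).  For recordings longer than 24 h the matching ZT bins of
successive days are averaged by default — a 48-h recording yields one 24-h
profile — with a concatenated (no averaging) mode available.

A *bout* is a maximal run of consecutive epochs in one state.  A *brief
arousal* is operationalized as a wake bout of at most ``max_epochs`` epochs
(default 2, i.e. <= 20 s at 10-s epochs) flanked by sleep (N or R) on both
sides; the threshold is deliberately configurable since conventions vary.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateAbsentError
from .io import Hypnogram, STATES

#: Expected ZT phase of each state for a nocturnal animal:
#: wake belongs in the dark phase, NREM and REM in the light phase.
EXPECTED_PHASE = {"W": "dark", "N": "light", "R": "light"}


def _bin_index(zt: np.ndarray, bin_h: float) -> np.ndarray:
    return np.floor((zt % 24.0) / bin_h).astype(int)


def _cycles_covered(hyp: Hypnogram, counts_per_bin: np.ndarray,
                    bin_h: float) -> np.ndarray:
    """How many times each ZT bin is (possibly fractionally) covered."""
    capacity = bin_h * 3600.0 / hyp.epoch_s
    return counts_per_bin / capacity


def state_minutes(hyp: Hypnogram, bin_h: float = 3.0,
                  average_days: bool = True) -> pd.DataFrame:
    """Minutes of W/N/R per ZT bin (bin label = initial ZT).

    With ``average_days`` the matching ZT bins of successive 24-h cycles are
    averaged, so each fully covered bin's state minutes sum to bin_h * 60.
    Partially covered bins are flagged with a warning.
    """
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ConfigurationError(f"bin width {bin_h} h must divide 24 h")
    n_bins = int(round(24.0 / bin_h))
    bins = _bin_index(hyp.zt_hours(), bin_h)
    counts = np.zeros((n_bins, len(STATES)))
    for j, state in enumerate(STATES):
        counts[:, j] = np.bincount(bins[hyp.states == state], minlength=n_bins)
    per_bin_total = counts.sum(axis=1)
    minutes = counts * hyp.epoch_s / 60.0
    if average_days:
        cycles = _cycles_covered(hyp, per_bin_total, bin_h)
        nonzero = cycles > 0
        frac = nonzero & ~np.isclose(cycles, np.round(cycles))
        if frac.any():
            warnings.warn(
                f"{int(frac.sum())} ZT bins only partially covered; "
                "their averaged minutes are over the covered fraction")
        minutes[nonzero] /= cycles[nonzero, None]
    labels = np.arange(n_bins) * bin_h
    out = pd.DataFrame(minutes, columns=list(STATES),
                       index=pd.Index(labels, name="zt_bin"))
    return out


def detect_bouts(hyp: Hypnogram) -> pd.DataFrame:
    """Run-length encoding of the hypnogram.

    Concatenating the bouts reconstructs the state sequence exactly.
    """
    s = hyp.states
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(s)]])
    return pd.DataFrame({
        "state": s[starts],
        "start_epoch": starts,
        "n_epochs": ends - starts,
        "duration_s": (ends - starts) * hyp.epoch_s,
    })


def state_changes(hyp: Hypnogram) -> int:
    """Number of adjacent epoch pairs with differing states (= bouts - 1)."""
    return int(np.sum(hyp.states[1:] != hyp.states[:-1]))


def brief_arousals(hyp: Hypnogram, max_epochs: int = 2, bin_h: float = 3.0,
                   average_days: bool = True) -> pd.Series:
    """Count of brief arousals per ZT bin (binned by bout-start ZT).

    A brief arousal is a wake bout of <= ``max_epochs`` epochs flanked by
    sleep (N or R) on both sides.  With ``average_days`` counts are averaged
    across 24-h cycles (and may therefore be fractional).
    """
    if max_epochs < 1:
        raise ConfigurationError("max_epochs must be >= 1")
    bouts = detect_bouts(hyp)
    is_sleep = np.isin(bouts["state"].to_numpy(), ("N", "R"))
    wake = bouts["state"].to_numpy() == "W"
    short = bouts["n_epochs"].to_numpy() <= max_epochs
    flanked = np.zeros(len(bouts), dtype=bool)
    if len(bouts) >= 3:
        flanked[1:-1] = is_sleep[:-2] & is_sleep[2:]
    keep = wake & short & flanked

    n_bins = int(round(24.0 / bin_h))
    zt = hyp.zt_hours()
    start_bins = _bin_index(zt[bouts["start_epoch"].to_numpy()[keep]], bin_h)
    counts = np.bincount(start_bins, minlength=n_bins).astype(float)
    if average_days:
        epoch_bins = _bin_index(zt, bin_h)
        cycles = _cycles_covered(
            hyp, np.bincount(epoch_bins, minlength=n_bins), bin_h)
        counts[cycles > 0] /= cycles[cycles > 0]
    return pd.Series(counts, index=pd.Index(np.arange(n_bins) * bin_h,
                                            name="zt_bin"),
                     name="brief_arousals")


def correct_phase_proportion(hyp: Hypnogram, state: str) -> float:
    """Fraction of a state's epochs occurring in its expected ZT phase.

    Expected phases for nocturnal animals: wake in the dark phase
    (ZT 12-24), NREM and REM in the light phase (ZT 0-12).
    """
    sel = hyp.states == state
    if not sel.any():
        raise StateAbsentError(f"state {state!r} absent from hypnogram")
    zt = hyp.zt_hours()[sel]
    in_light = zt < 12.0
    if EXPECTED_PHASE[state] == "light":
        return float(np.mean(in_light))
    return float(np.mean(~in_light))


def architecture_summary(hyp: Hypnogram, animal: str = "",
                         brief_arousal_max_epochs: int = 2) -> pd.DataFrame:
    """One-row per-animal summary of the headline architecture metrics."""
    daily = state_minutes(hyp, bin_h=24.0)
    bouts = detect_bouts(hyp)
    n_days = max(hyp.duration_h / 24.0, 1e-9)
    row = {"animal": animal}
    for state in STATES:
        row[f"{state}_minutes"] = float(daily.loc[0, state])
        sb = bouts[bouts["state"] == state]
        row[f"{state}_bouts_per_24h"] = len(sb) / n_days
        row[f"{state}_mean_bout_s"] = (float(sb["duration_s"].mean())
                                       if len(sb) else np.nan)
        try:
            row[f"{state}_correct_phase"] = correct_phase_proportion(hyp, state)
        except StateAbsentError:
            row[f"{state}_correct_phase"] = np.nan
    row["state_changes_per_24h"] = state_changes(hyp) / n_days
    row["brief_arousals_per_24h"] = float(
        brief_arousals(hyp, max_epochs=brief_arousal_max_epochs,
                       average_days=False).sum()) / n_days
    return pd.DataFrame([row])
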
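"""Sleep-spindle detection with dual SD thresholds on a moving-window RMS.

The EEG is zero-phase band-passed to the sigma band (11-15 Hz) and reduced
to an envelope: RMS over an 800-ms window stepped by 200 ms.  Windows that
overlap any non-NREM epoch are masked out.  Thresholds are relative,
mu + k*sigma of the NREM-only envelope distribution of that recording:
candidate events are maximal runs of windows above the *primary* threshold
(k = 0.5) and are kept only if at least one window exceeds the *secondary*
threshold (k = 2.0).  Nearby events are merged and implausibly short or
long ones discarded.

Timing convention: each window's RMS is assigned to the window *centre*,
and an event's extent is one 200-ms step per supra-primary window
(start = first centre - step/2).  This makes a burst that elevates n
windows report a duration of n steps, so detected durations are quantized
to the step and match planted durations to within one step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError
from .io import Hypnogram, Recording, epoch_grid


@dataclass(frozen=True)
class SpindleParams:
    band: tuple[float, float] = (11.0, 15.0)
    window_ms: float = 800.0
    step_ms: float = 200.0
    primary_k: float = 0.5       # SD units above the NREM envelope mean
    secondary_k: float = 2.0     # SD units; at least one window must exceed
    min_duration_s: float = 0.5
    max_duration_s: float = 3.0
    merge_gap_ms: float = 200.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.window_ms % self.step_ms != 0:
            raise ConfigurationError("step_ms must divide window_ms")
        if not (0 < self.primary_k < self.secondary_k):
            raise ConfigurationError("need 0 < primary_k < secondary_k")
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ConfigurationError("need 0 < min_duration < max_duration")


@dataclass
class SigmaEnvelope:
    """Moving-window RMS of the sigma-band EEG with an NREM validity mask."""

    values: np.ndarray      # RMS per window
    nrem_mask: np.ndarray   # bool per window; False = overlaps non-NREM
    step_s: float
    window_s: float
    start_s: float = 0.0    # time of the first window's *start*

    @property
    def centers_s(self) -> np.ndarray:
        return (self.start_s + self.window_s / 2.0
                + np.arange(len(self.values)) * self.step_s)


def sigma_envelope(recording: Recording, hypnogram: Hypnogram,
                   params: SpindleParams | None = None,
                   channel: str = "EEG1") -> SigmaEnvelope:
    """Band-pass to sigma, then RMS over stepped windows; mask non-NREM.

    Window count before masking is floor((n_samples - window)/step) + 1.
    """
    params = params or SpindleParams()
    fs = recording.fs
    n_win = params.window_ms * fs / 1000.0
    n_step = params.step_ms * fs / 1000.0
    if abs(n_win - round(n_win)) > 1e-9 or abs(n_step - round(n_step)) > 1e-9:
        raise ConfigurationError(
            f"window/step ({params.window_ms}/{params.step_ms} ms) not an "
            f"integer number of samples at fs={fs}")
    n_win, n_step = int(round(n_win)), int(round(n_step))
    x = recording.channel(channel)
    if len(x) < n_win:
        raise ConfigurationError("recording shorter than one envelope window")

    if np.any(x != 0):
        sos = sps.butter(params.filter_order, list(params.band),
                         btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    csum = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])
    starts = np.arange(0, len(x) - n_win + 1, n_step)
    rms = np.sqrt((csum[starts + n_win] - csum[starts]) / n_win)

    grid = epoch_grid(recording, hypnogram.epoch_s)
    n_per = grid[0, 1] - grid[0, 0]
    n_scored = grid[-1, 1]
    is_nrem_epoch = hypnogram.states[:len(grid)] == "N"
    first_ep = starts // n_per
    last_ep = (starts + n_win - 1) // n_per
    in_range = (starts + n_win) <= n_scored
    mask = in_range.copy()
    mask[in_range] = (is_nrem_epoch[first_ep[in_range]]
                      & is_nrem_epoch[last_ep[in_range]])
    return SigmaEnvelope(values=rms, nrem_mask=mask,
                         step_s=params.step_ms / 1000.0,
                         window_s=params.window_ms / 1000.0)


def detect_spindles(envelope: SigmaEnvelope,
                    params: SpindleParams | None = None) -> pd.DataFrame:
    """Threshold the envelope into spindle events.

    Returns a DataFrame with columns start_s, duration_s, peak_envelope,
    rms_amplitude (RMS of the event's window values), n_windows.
    Amplitude columns scale with the signal; counts and durations do not,
    since both thresholds are relative to the NREM envelope distribution.
    """
    params = params or SpindleParams()
    vals = np.asarray(envelope.values, dtype=float)
    mask = np.asarray(envelope.nrem_mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("envelope has no NREM windows")
    nrem_vals = vals[mask]
    mu, sd = float(np.mean(nrem_vals)), float(np.std(nrem_vals))
    cols = ["start_s", "duration_s", "peak_envelope", "rms_amplitude",
            "n_windows"]
    if sd == 0.0:
        warnings.warn("degenerate (constant) NREM envelope; no events")
        return pd.DataFrame(columns=cols)
    thr1 = mu + params.primary_k * sd
    thr2 = mu + params.secondary_k * sd

    above = (vals > thr1) & mask
    edges = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(edges == 1) + 1
    run_ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        run_starts = np.concatenate([[0], run_starts])
    if above[-1]:
        run_ends = np.concatenate([run_ends, [len(vals)]])

    # secondary-threshold veto
    keep = [(s, e) for s, e in zip(run_starts, run_ends)
            if np.any(vals[s:e] > thr2)]

    # merge events separated by less than merge_gap_ms
    merged: list[list[int]] = []
    gap_windows = params.merge_gap_ms / 1000.0 / envelope.step_s
    for s, e in keep:
        if merged and (s - merged[-1][1]) < gap_windows:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    step = envelope.step_s
    centers = envelope.centers_s
    rows = []
    for s, e in merged:
        duration = (e - s) * step
        if not (params.min_duration_s <= duration <= params.max_duration_s):
            continue
        seg = vals[s:e]
        rows.append({
            "start_s": centers[s] - step / 2.0,
            "duration_s": duration,
            "peak_envelope": float(seg.max()),
            "rms_amplitude": float(np.sqrt(np.mean(seg ** 2))),
            "n_windows": int(e - s),
        })
    return pd.DataFrame(rows, columns=cols)


def spindle_summary(events: pd.DataFrame, hypnogram: Hypnogram,
                    animal: str = "") -> dict:
    """Per-animal spindle metrics: count/24 h, duration, density, amplitude."""
    nrem_min = hypnogram.minutes("N")
    n = len(events)
    out = {
        "animal": animal,
        "n_spindles": n,
        "spindles_per_24h": n / max(hypnogram.duration_h / 24.0, 1e-12),
        "mean_duration_s": float(events["duration_s"].mean()) if n else np.nan,
        "mean_rms_amplitude": (float(events["rms_amplitude"].mean())
                               if n else np.nan),
    }
    if nrem_min <= 0:
        warnings.warn("zero NREM minutes: spindle density undefined")
        out["density_per_min_nrem"] = np.nan
    else:
        out["density_per_min_nrem"] = n / nrem_min
    return out


def detect_in_recording(recording: Recording, hypnogram: Hypnogram,
                        params: SpindleParams | None = None,
                        channel: str = "EEG1") -> pd.DataFrame:
    """Convenience: envelope + detection in one call."""
    params = params or SpindleParams()
    env = sigma_envelope(recording, hypnogram, params, channel=channel)
    return detect_spindles(env, params)
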
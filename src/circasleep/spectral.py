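"""Per-epoch power spectra, band powers and state-wise relative PSD.

Bands follow the rodent sleep-EEG convention used throughout the package:
delta 0.5-4, theta 4-8, alpha 8-11, sigma 11-15 and beta 15-30 Hz, with
0.5-30 Hz as the total range all fractions are taken against.

PSDs are Welch estimates with 2-s Hann segments and 50% overlap inside each
10-s epoch, giving 0.5 Hz resolution (matching the delta lower edge).
Relative PSD normalizes each epoch's spectrum to its own total 0.5-30 Hz
power *before* averaging across a state's epochs, which de-weights
high-power artifact epochs; normalizing the state-mean spectrum instead is
available as a switch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, StateAbsentError
from .io import Hypnogram, Recording, epoch_grid

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 11.0),
    "sigma": (11.0, 15.0),
    "beta": (15.0, 30.0),
}

#: Feature columns consumed by the vigilance-state scorer.
FEATURE_COLUMNS = ["delta", "theta", "alpha", "sigma", "beta",
                   "log_total_power", "log_emg_rms"]


@dataclass(frozen=True)
class BandScheme:
    """Named, ordered, non-overlapping frequency bands within a total range."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    total_range: tuple[float, float] = (0.5, 30.0)

    def __post_init__(self) -> None:
        lo_t, hi_t = self.total_range
        prev_hi = lo_t
        for name, (lo, hi) in self.bands.items():
            if not (lo < hi):
                raise ConfigurationError(f"band {name}: empty interval")
            if lo < prev_hi - 1e-12:
                raise ConfigurationError(
                    f"band {name} overlaps or is out of order")
            if lo < lo_t or hi > hi_t + 1e-12:
                raise ConfigurationError(
                    f"band {name} outside total range {self.total_range}")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return list(self.bands)


def epoch_psd(x: np.ndarray, fs: float, seg_s: float = 2.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of one or many epochs.

    ``x`` has shape (..., n_samples); Hann segments of ``seg_s`` seconds with
    50% overlap.  Integrated PSD is Parseval-consistent with the (per-segment
    detrended) signal variance.  Constant signals yield an all-zero spectrum.
    """
    nperseg = int(round(seg_s * fs))
    n = np.asarray(x).shape[-1]
    if n < nperseg:
        raise ConfigurationError(
            f"epoch of {n} samples shorter than one {seg_s}-s Welch segment")
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant",
                           axis=-1)
    return freqs, psd


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                scheme: BandScheme | None = None) -> pd.DataFrame:
    """Integrate PSD over each band: rectangular sum of psd*df on [lo, hi).

    ``psd`` has shape (n_epochs, n_freqs) or (n_freqs,).  Returns a DataFrame
    with one column per band plus ``total_power`` over the scheme's total
    range.  Because the default bands tile the total range, band powers sum
    to the total exactly.
    """
    scheme = scheme or BandScheme()
    psd = np.atleast_2d(psd)
    df = float(freqs[1] - freqs[0])
    out = {}
    for name, (lo, hi) in scheme.bands.items():
        mask = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
        out[name] = psd[:, mask].sum(axis=1) * df
    lo_t, hi_t = scheme.total_range
    mask = (freqs >= lo_t - 1e-9) & (freqs < hi_t - 1e-9)
    out["total_power"] = psd[:, mask].sum(axis=1) * df
    return pd.DataFrame(out)


def epoch_spectra(recording: Recording, epoch_s: float = 10.0,
                  channel: str = "EEG1", seg_s: float = 2.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of every epoch of one channel: (freqs, psd[n_epochs, n_f])."""
    grid = epoch_grid(recording, epoch_s)
    x = recording.channel(channel)
    n_per = grid[0, 1] - grid[0, 0]
    epochs = x[:grid[-1, 1]].reshape(len(grid), n_per)
    return epoch_psd(epochs, recording.fs, seg_s=seg_s)


def emg_rms(recording: Recording, epoch_s: float = 10.0,
            channel: str = "EMG", band: tuple[float, float] = (10.0, 100.0),
            order: int = 4) -> np.ndarray:
    """Per-epoch RMS of the band-passed EMG (band capped below Nyquist)."""
    grid = epoch_grid(recording, epoch_s)
    x = recording.channel(channel)
    nyq = recording.fs / 2.0
    lo, hi = band[0], min(band[1], 0.95 * nyq)
    if lo >= hi:
        raise ConfigurationError(f"EMG band {band} empty below Nyquist {nyq}")
    if np.all(x == 0):
        filt = x
    else:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=recording.fs,
                         output="sos")
        filt = sps.sosfiltfilt(sos, x)
    n_per = grid[0, 1] - grid[0, 0]
    seg = filt[:grid[-1, 1]].reshape(len(grid), n_per)
    return np.sqrt(np.mean(seg ** 2, axis=1))


def extract_features(recording: Recording, epoch_s: float = 10.0,
                     scheme: BandScheme | None = None,
                     eeg_channel: str = "EEG1",
                     emg_channel: str = "EMG") -> pd.DataFrame:
    """Per-epoch feature matrix for vigilance-state classification.

    Columns: the five band fractions of total 0.5-30 Hz power, log total
    power, log EMG RMS (the scorer's 7 features), plus absolute powers,
    ``emg_rms`` and an ``unscorable`` flag for epochs containing NaNs.
    """
    scheme = scheme or BandScheme()
    freqs, psd = epoch_spectra(recording, epoch_s, channel=eeg_channel)
    powers = band_powers(freqs, psd, scheme)
    total = powers["total_power"].to_numpy()
    rms = emg_rms(recording, epoch_s, channel=emg_channel)

    grid = epoch_grid(recording, epoch_s)
    n_per = grid[0, 1] - grid[0, 0]
    eeg = recording.channel(eeg_channel)[:grid[-1, 1]].reshape(len(grid), n_per)
    unscorable = ~np.isfinite(eeg).all(axis=1)
    unscorable |= ~np.isfinite(psd).all(axis=1)
    unscorable |= ~np.isfinite(rms)

    tiny = np.finfo(float).tiny
    feats = pd.DataFrame(index=pd.RangeIndex(len(grid), name="epoch_index"))
    safe_total = np.where(total > 0, total, 1.0)
    for name in scheme.names:
        feats[name] = powers[name].to_numpy() / safe_total
    feats["total_power"] = total
    feats["emg_rms"] = rms
    feats["log_total_power"] = np.log(np.maximum(total, tiny))
    feats["log_emg_rms"] = np.log(np.maximum(rms, tiny))
    feats["unscorable"] = unscorable
    feats.loc[unscorable, FEATURE_COLUMNS] = 0.0
    if unscorable.any():
        warnings.warn(f"{int(unscorable.sum())} epochs flagged unscorable")
    return feats


def relative_psd(psd: np.ndarray, freqs: np.ndarray, hypnogram: Hypnogram,
                 state: str, total_range: tuple[float, float] = (0.5, 30.0),
                 phase: str | None = None,
                 per_epoch_normalization: bool = True) -> pd.Series:
    """Mean normalized spectrum of one vigilance state.

    Each epoch's spectrum on the total-range grid is normalized to its own
    total power, then averaged over the state's epochs (optionally restricted
    to the ``"light"`` or ``"dark"`` phase); the result sums to 1 over the
    grid.  With ``per_epoch_normalization=False`` the state-mean spectrum is
    normalized instead.
    """
    psd = np.atleast_2d(psd)
    if psd.shape[0] != hypnogram.n_epochs:
        raise ConfigurationError("PSD rows do not match hypnogram epochs")
    sel = hypnogram.states == state
    if phase is not None:
        zt = hypnogram.zt_hours()
        in_light = zt < 12.0
        sel &= in_light if phase == "light" else ~in_light
    if not sel.any():
        raise StateAbsentError(
            f"state {state!r} absent"
            + (f" in {phase} phase" if phase else ""))
    lo, hi = total_range
    mask = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
    sub = psd[np.flatnonzero(sel)][:, mask]
    totals = sub.sum(axis=1)
    ok = totals > 0
    if not ok.any():
        raise StateAbsentError(f"state {state!r} has only zero-power epochs")
    if per_epoch_normalization:
        mean = (sub[ok] / totals[ok, None]).mean(axis=0)
    else:
        mean = sub[ok].mean(axis=0)
    mean = mean / mean.sum()
    return pd.Series(mean, index=pd.Index(freqs[mask], name="frequency_hz"),
                     name=f"relative_power_{state}")


def relative_psd_table(psd: np.ndarray, freqs: np.ndarray,
                       hypnogram: Hypnogram, animal: str = "",
                       states: tuple[str, ...] = ("W", "N", "R"),
                       **kwargs) -> pd.DataFrame:
    """Long-format relative PSD: animal, state, frequency_hz, relative_power."""
    rows = []
    for state in states:
        try:
            rel = relative_psd(psd, freqs, hypnogram, state, **kwargs)
        except StateAbsentError:
            continue
        rows.append(pd.DataFrame({
            "animal": animal, "state": state,
            "frequency_hz": rel.index.to_numpy(),
            "relative_power": rel.to_numpy()}))
    return (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["animal", "state", "frequency_hz",
                                       "relative_power"]))
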
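"""Recordings, hypnograms and their on-disk formats.

EEG/EMG recordings travel as standard 16-bit EDF.  Reading goes through MNE;
writing uses a minimal EDF writer below (one data record per second, physical
range fitted per channel).  The light schedule is carried in a YAML sidecar
rather than inferred from the EDF start time, so the zeitgeber-time (ZT)
convention — ZT0 = lights on, ZT12 = lights off under 12:12 LD — is explicit.

Hypnograms are per-epoch vigilance-state labels (W/N/R) on a fixed epoch grid
(10 s by default) anchored to a ZT start time.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError

STATES = ("W", "N", "R")
DEFAULT_CHANNELS = ("EEG1", "EEG2", "EMG")


@dataclass
class Recording:
    """Multichannel signal with sampling rate and ZT anchor.

    ``data`` has shape (n_channels, n_samples); all channels share ``fs``.
    Signal values are in arbitrary units consistent across channels.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    start_zt: float = 0.0
    lights_on_zt: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("recording data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        self.start_zt = float(self.start_zt) % 24.0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise FormatError(f"channel {name!r} not in {self.channel_names}")
        return self.data[i]


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels on a ZT timeline."""

    states: np.ndarray
    epoch_s: float = 10.0
    start_zt: float = 0.0
    labels_source: str = "simulated"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.size == 0:
            raise ConfigurationError("hypnogram must contain at least one epoch")
        if self.epoch_s <= 0:
            raise ConfigurationError("epoch length must be positive")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise FormatError(f"unknown state labels {sorted(bad)}")
        self.start_zt = float(self.start_zt) % 24.0

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_s / 3600.0

    def zt_hours(self) -> np.ndarray:
        """ZT of each epoch midpoint, wrapped to [0, 24)."""
        mid = (np.arange(self.n_epochs) + 0.5) * self.epoch_s / 3600.0
        return (self.start_zt + mid) % 24.0

    def minutes(self, state: str) -> float:
        return float(np.sum(self.states == state)) * self.epoch_s / 60.0


def epoch_grid(recording: Recording, epoch_s: float = 10.0) -> np.ndarray:
    """Half-open sample intervals [i*n, (i+1)*n) tiling the recording.

    The trailing partial epoch is discarded.  Returns an (n_epochs, 2) int
    array of [start, stop) sample indices.
    """
    n_per = recording.fs * epoch_s
    if abs(n_per - round(n_per)) > 1e-9 or round(n_per) < 1:
        raise ConfigurationError(
            f"epoch_s={epoch_s} x fs={recording.fs} is not a positive integer "
            "number of samples")
    n_per = int(round(n_per))
    n_epochs = recording.n_samples // n_per
    starts = np.arange(n_epochs, dtype=int) * n_per
    return np.stack([starts, starts + n_per], axis=1)


# ---------------------------------------------------------------------------
# EDF writing (minimal 16-bit writer; no writer library is depended on)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_recording(recording: Recording, path: str | Path,
                    physical_dim: str = "uV") -> Path:
    """Write a Recording as standard EDF (16-bit, 1-s data records).

    The physical range of each channel is fitted to its data, so round-trips
    are exact up to one 16-bit quantization step of that range.  A trailing
    partial second is truncated.  A YAML sidecar ``<path>.yaml`` carries the
    light-schedule anchor (``start_zt``, ``lights_on_zt``).
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise FormatError("recording shorter than one 1-s EDF data record")
    n_ch = len(recording.channel_names)

    data = recording.data[:, :n_records * fs]
    phys_min, phys_max, digital = [], [], []
    for row in data:
        amax = float(np.max(np.abs(row)))
        amax = amax if amax > 0 else 1.0
        lo, hi = -amax, amax
        scale = (hi - lo) / (32767 - (-32768))
        dig = np.round((row - lo) / scale).astype(np.int64) - 32768
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),                       # patient id
        _pad("Startdate X X X X", 80),             # recording id
        _pad("01.01.00", 8), _pad("00.00.00", 8),  # date, time (unused; ZT in sidecar)
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),                              # record duration, s
        _pad(str(n_ch), 4),
    ])
    fields = [
        (16, list(recording.channel_names)),
        (80, [""] * n_ch),                          # transducer
        (8, [physical_dim] * n_ch),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, ["-32768"] * n_ch),
        (8, ["32767"] * n_ch),
        (80, [""] * n_ch),                          # prefiltering
        (8, [str(fs)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(b"".join(_pad(v, w) for v in vals) for w, vals in fields)

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch][r * fs:(r + 1) * fs].tobytes())

    write_sidecar(recording, path.with_suffix(path.suffix + ".yaml"))
    return path


def write_sidecar(recording: Recording, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"start_zt": float(recording.start_zt),
                        "lights_on_zt": float(recording.lights_on_zt)}, fh)


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_recording(path: str | Path,
                   require_channels: tuple[str, ...] = DEFAULT_CHANNELS,
                   start_zt: float | None = None) -> Recording:
    """Read an EDF recording (via MNE); ZT anchor from the YAML sidecar.

    Raises FormatError if any of ``require_channels`` is missing or sampling
    rates are inconsistent.
    """
    import mne  # local import: heavy dependency, only needed for reading

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise FormatError(f"unreadable EDF {path}: {exc}") from exc
    missing = [c for c in require_channels if c not in raw.ch_names]
    if missing:
        raise FormatError(f"EDF {path} missing channels {missing}")
    data = raw.get_data(picks=list(require_channels), units="uV")
    if start_zt is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = read_sidecar(sidecar) if sidecar.exists() else {}
        start_zt = float(meta.get("start_zt", 0.0))
        lights_on = float(meta.get("lights_on_zt", 0.0))
    else:
        lights_on = 0.0
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channel_names=tuple(require_channels),
                     start_zt=start_zt, lights_on_zt=lights_on)


def edf_quantization_step(recording: Recording) -> np.ndarray:
    """Per-channel physical quantization step the EDF writer will use."""
    amax = np.max(np.abs(recording.data), axis=1)
    amax = np.where(amax > 0, amax, 1.0)
    return 2 * amax / 65535.0


# ---------------------------------------------------------------------------
# Hypnogram / label CSVs
# ---------------------------------------------------------------------------

def write_hypnogram_csv(hyp: Hypnogram, path: str | Path) -> Path:
    df = pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "zt_hours": np.round(hyp.zt_hours(), 6),
        "state": hyp.states,
    })
    df.to_csv(path, index=False)
    return Path(path)


def read_hypnogram_csv(path: str | Path, epoch_s: float = 10.0,
                       labels_source: str = "human") -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "state"):
        if col not in df.columns:
            raise FormatError(f"hypnogram CSV {path} lacks column {col!r}")
    df = df.sort_values("epoch_index")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError(f"hypnogram CSV {path} has gaps in epoch_index")
    start_zt = 0.0
    if "zt_hours" in df.columns and len(df):
        start_zt = float(df["zt_hours"].iloc[0]) - 0.5 * epoch_s / 3600.0
    return Hypnogram(states=df["state"].to_numpy(), epoch_s=epoch_s,
                     start_zt=start_zt, labels_source=labels_source)


def read_labels_csv(path: str | Path) -> dict[int, str]:
    """Partial human labels: CSV with epoch_index and state for a fraction
    of the epochs."""
    df = pd.read_csv(path)
    for col in ("epoch_index", "state"):
        if col not in df.columns:
            raise FormatError(f"label CSV {path} lacks column {col!r}")
    bad = set(df["state"].unique()) - set(STATES)
    if bad:
        raise FormatError(f"label CSV {path} has unknown states {sorted(bad)}")
    return dict(zip(df["epoch_index"].astype(int), df["state"]))


def write_labels_csv(labels: dict[int, str], path: str | Path) -> Path:
    items = sorted(labels.items())
    pd.DataFrame(items, columns=["epoch_index", "state"]).to_csv(path, index=False)
    return Path(path)
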
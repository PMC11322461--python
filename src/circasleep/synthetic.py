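"""Ground-truthed synthetic cohorts: hypnograms, EEG/EMG signals, maze tables.

The generator emulates the study design this package analyzes: a 2x2x2
cohort (genotype WT/TG x sex F/M x feeding restricted to the light or dark
phase) recorded for 48 h under 12:12 LD at 250 Hz with 10-s epochs.

Hypnograms come from a per-epoch persistence ("semi-Markov") chain over
{W, N, R} with geometric dwell times.  At each epoch the animal stays in
its state with a state-specific persistence probability, otherwise it
redraws a state from a bin-specific redraw distribution.  That distribution
is solved in closed form per ZT bin so the chain's stationary occupancy
equals the configured profile exactly, under the rodent transition topology
W<->N, N->R, R->W (REM is entered only from NREM; redraws that would make
an illegal move are redirected and the solve compensates).

Signals are state-conditioned mixtures of band-limited noise (NREM
delta-dominant, REM theta-dominant with EMG atonia, wake mixed with high
EMG), in arbitrary units with ~unit background scale.  Spindles are
Hann-windowed 12.5-Hz bursts planted at Poisson times within NREM, with
amplitude set as a configurable multiple (the envelope SNR) of the
background sigma-band RMS.  Every planted event is recorded as ground
truth.

Barnes-maze tables draw trial latencies from a truncated exponentially
decaying learning curve with group-dependent rate, errors correlated with
latency, and an optional negative coupling from an animal's REM amount to
its latencies (more REM -> faster learning), mirroring the REM-cognition
association the analysis layer is meant to detect.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError
from .io import Hypnogram, Recording, STATES

GENOTYPES = ("WT", "TG")
SEXES = ("F", "M")
FEEDINGS = ("light_fed", "dark_fed")
ALL_GROUPS = tuple((g, s, f) for g in GENOTYPES for s in SEXES
                   for f in FEEDINGS)

_ALLOWED = {("W", "N"), ("N", "W"), ("N", "R"), ("R", "W")}
_IDX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design: groups, recording duration, epoching, sampling, seed."""

    n_per_group: int = 6
    groups: tuple[tuple[str, str, str], ...] = ALL_GROUPS
    duration_h: float = 48.0
    epoch_s: float = 10.0
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.duration_h <= 0 or self.duration_h % 24.0 != 0:
            raise ConfigurationError("duration_h must be a positive multiple of 24")
        n = self.fs * self.epoch_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ConfigurationError("fs x epoch_s must be an integer >= 1")
        for g in self.groups:
            if g[0] not in GENOTYPES or g[1] not in SEXES or g[2] not in FEEDINGS:
                raise ConfigurationError(f"unknown group {g}")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.epoch_s))


def default_state_profile() -> np.ndarray:
    """Hourly W/N/R occupancy targets for an undisturbed nocturnal animal.

    Light phase (ZT0-12): mostly asleep (NREM 0.55, REM 0.10); dark phase:
    mostly awake.  Rows are ZT hours 0..23, columns W/N/R; each row sums
    to 1.
    """
    prof = np.zeros((24, 3))
    prof[:12] = (0.35, 0.55, 0.10)
    prof[12:] = (0.78, 0.19, 0.03)
    return prof


@dataclass(frozen=True)
class EffectSpec:
    """Group-dependent effect parameters for the generator.

    The contrasts of interest (TG sleep loss, light-fed rhythm
    transposition, REM-cognition coupling) are qualitative; their magnitudes
    here are free parameters with defaults chosen to be realistic for mouse
    sleep, documented in the methods note.
    """

    base_state_profile: np.ndarray = field(default_factory=default_state_profile)
    #: multiplicative occupancy deltas applied to the TG genotype
    genotype_effects: dict = field(default_factory=lambda: {
        "nrem_scale": 0.85, "rem_scale": 0.75})
    #: circular transposition of light-phase NREM into late dark (light-fed)
    feeding_effects: dict = field(default_factory=lambda: {
        "transposition_fraction": 0.35, "transposition_span_h": 3})
    persistence: dict = field(default_factory=lambda: {
        "W": 0.92, "N": 0.90, "R": 0.85})
    spindle_rate: float = 3.0            # events per minute of NREM
    spindle_duration_s: tuple[float, float] = (1.0, 0.3)   # mean, sd
    spindle_duration_bounds: tuple[float, float] = (0.5, 2.0)
    spindle_snr: float = 5.0             # burst envelope / background sigma RMS
    spindle_freq_hz: float = 12.5
    noise_sd: float = 1.0
    state_gains: dict = field(default_factory=lambda: {
        "W": {"delta": 0.6, "theta": 0.8, "broad": 1.0},
        "N": {"delta": 2.0, "theta": 0.5, "broad": 0.5},
        "R": {"delta": 0.3, "theta": 2.0, "broad": 0.4}})
    emg_gains: dict = field(default_factory=lambda: {
        "W": 1.0, "N": 0.2, "R": 0.05})
    behavior_effects: dict = field(default_factory=lambda: {
        "baseline_latency_s": 140.0,
        "asymptote_latency_s": 15.0,
        "decay_per_day": {("WT", "dark_fed"): 0.55, ("WT", "light_fed"): 0.35,
                          ("TG", "dark_fed"): 0.35, ("TG", "light_fed"): 0.20},
        "latency_sigma": 0.30,           # lognormal trial noise (log scale)
        "animal_sigma": 0.15,            # lognormal between-animal spread
        "error_rate_per_s": 0.08,
        "center_time_mean_s": {"default": 6.0, ("TG", "F"): 18.0},
        "center_sigma": 0.5,
        "freezing_mean_s": 2.0,
        "rem_latency_coupling": 0.35})

    def __post_init__(self) -> None:
        prof = np.asarray(self.base_state_profile, dtype=float)
        if prof.shape != (24, 3):
            raise ConfigurationError("base_state_profile must be (24, 3)")
        if np.any(prof < 0) or not np.allclose(prof.sum(axis=1), 1.0):
            raise ConfigurationError(
                "occupancy probabilities must be >= 0 and sum to 1 per bin")
        if self.spindle_rate < 0:
            raise ConfigurationError("spindle_rate must be >= 0")
        if any(v < 0 for v in
               self.behavior_effects["decay_per_day"].values()):
            raise ConfigurationError("decay rates must be >= 0")


def group_profile(effects: EffectSpec,
                  group: tuple[str, str, str]) -> np.ndarray:
    """Apply genotype and feeding-time effects to the base occupancy profile."""
    genotype, _sex, feeding = group
    prof = np.asarray(effects.base_state_profile, dtype=float).copy()
    if genotype == "TG":
        prof[:, _IDX["N"]] *= effects.genotype_effects["nrem_scale"]
        prof[:, _IDX["R"]] *= effects.genotype_effects["rem_scale"]
        prof[:, _IDX["W"]] = 1.0 - prof[:, _IDX["N"]] - prof[:, _IDX["R"]]
    if feeding == "light_fed":
        frac = effects.feeding_effects["transposition_fraction"]
        span = int(effects.feeding_effects["transposition_span_h"])
        if frac > 0 and span > 0:
            src = np.arange(span)            # start of light phase
            dst = np.arange(24 - span, 24)   # end of dark phase
            moved = frac * prof[src, _IDX["N"]]
            prof[src, _IDX["N"]] -= moved
            prof[src, _IDX["W"]] += moved
            add = np.full(span, moved.sum() / span)
            headroom = prof[dst, _IDX["W"]] - 0.02
            if np.any(add > headroom):
                warnings.warn("transposition clipped by wake headroom")
                add = np.minimum(add, np.maximum(headroom, 0.0))
            prof[dst, _IDX["N"]] += add
            prof[dst, _IDX["W"]] -= add
    if np.any(prof < -1e-12):
        raise ConfigurationError("effect combination drove occupancy negative")
    prof = np.clip(prof, 0.0, None)
    return prof / prof.sum(axis=1, keepdims=True)


def _chain_parameters(pi: np.ndarray, p_stay: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin redraw distribution (and possibly adjusted persistence)
    making the chain's stationary occupancy equal the target ``pi``.

    With a = pi_W(1-p_W), b = pi_N(1-p_N), c = pi_R(1-p_R), flow balance of
    the persistence+redraw chain under the legal topology (W-redraws of R
    redirected to N, R-redraws of N redirected to W) gives
    q_R = c/(b+c),  q_W = (a - c(1-q_R))/(a+b),  q_N = 1 - q_W - q_R,
    which is feasible iff b(b+c) >= a*c.  Very wake-dominant bins can
    violate that; wake persistence is then raised for the bin (longer wake
    bouts) until the balance is solvable, keeping occupancy exact.
    """
    pw, pn, pr = (float(pi[_IDX[s]]) for s in STATES)
    if pr > 0 and pn == 0:
        raise ConfigurationError(
            "REM occupancy requires NREM occupancy (REM is entered from NREM)")
    p = p_stay.astype(float).copy()
    b = pn * (1 - p[_IDX["N"]])
    c = pr * (1 - p[_IDX["R"]])
    a = pw * (1 - p[_IDX["W"]])
    if c > 0 and a * c > b * (b + c):
        a = 0.95 * b * (b + c) / c
        p[_IDX["W"]] = 1.0 - a / pw if pw > 0 else p[_IDX["W"]]
    q = np.zeros(3)
    q_r = c / (b + c) if (b + c) > 0 else 0.0
    denom = a + b
    q_w = ((a - c * (1 - q_r)) / denom if denom > 0
           else (1.0 if a > 0 else 0.0))
    q[_IDX["R"]] = q_r
    q[_IDX["W"]] = min(max(q_w, 0.0), 1.0 - q_r)
    q[_IDX["N"]] = max(1.0 - q[_IDX["R"]] - q[_IDX["W"]], 0.0)
    s = q.sum()
    return p, (q / s if s > 0 else np.array([1.0, 0.0, 0.0]))


def simulate_hypnogram(config: CohortConfig, effects: EffectSpec,
                       group: tuple[str, str, str],
                       rng: np.random.Generator | None = None,
                       start_zt: float = 0.0,
                       allowed_transitions: set | None = None) -> Hypnogram:
    """Simulate one animal's ground-truth hypnogram.

    ``allowed_transitions`` exists only to validate custom topologies: a
    topology that lets REM be entered from wake is a configuration error.
    """
    if group not in config.groups:
        raise ConfigurationError(f"group {group} not in config.groups")
    if allowed_transitions is not None:
        if ("W", "R") in allowed_transitions:
            raise ConfigurationError("REM must not be reachable from Wake")
        if allowed_transitions != _ALLOWED:
            raise ConfigurationError(
                f"unsupported transition topology; expected {_ALLOWED}")
    rng = rng or np.random.default_rng(config.seed)
    prof = group_profile(effects, group)
    p_base = np.array([effects.persistence[s] for s in STATES])
    solved = [_chain_parameters(prof[h], p_base) for h in range(24)]
    p_stay_h = np.stack([p for p, _ in solved])       # (24, 3)
    q_cum = np.cumsum(np.stack([q for _, q in solved]), axis=1)

    n = config.n_epochs
    hours = ((start_zt + (np.arange(n) + 0.5) * config.epoch_s / 3600.0)
             % 24.0).astype(int)
    u = rng.random(n)
    v = rng.random(n)
    # redirects keeping the topology legal: from W, R->N; from R, N->W
    redirect = np.array([[0, 1, 1],      # from W
                         [0, 1, 2],      # from N
                         [0, 0, 2]])     # from R
    states = np.empty(n, dtype=np.int8)
    s = int(np.searchsorted(np.cumsum(prof[hours[0]]), v[0], side="right"))
    s = min(s, 2)
    states[0] = s
    for i in range(1, n):
        h = hours[i]
        if u[i] >= p_stay_h[h, s]:
            t = int(np.searchsorted(q_cum[h], v[i], side="right"))
            s = int(redirect[s, min(t, 2)])
        states[i] = s
    labels = np.array(STATES)[states]
    return Hypnogram(states=labels, epoch_s=config.epoch_s,
                     start_zt=start_zt, labels_source="simulated")


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _bandpassed_noise(rng: np.random.Generator, n: int, fs: float,
                      band: tuple[float, float], order: int = 4) -> np.ndarray:
    hi = min(band[1], 0.45 * fs)  # keep the upper edge below Nyquist
    sos = sps.butter(order, [band[0], hi], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


def _peak_window_rms(y: np.ndarray, n_win: int) -> float:
    """Largest RMS any length-``n_win`` window can capture of burst ``y``."""
    pad = np.concatenate([np.zeros(n_win), y ** 2, np.zeros(n_win)])
    cs = np.concatenate([[0.0], np.cumsum(pad)])
    sums = cs[n_win:] - cs[:-n_win]
    return float(np.sqrt(sums.max() / n_win))


def _plant_spindles(eeg: np.ndarray, hypnogram: Hypnogram, fs: float,
                    effects: EffectSpec,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Insert Hann-windowed sigma bursts into NREM; returns the event table."""
    cols = ["start_s", "duration_s", "amplitude", "truncated"]
    if effects.spindle_rate <= 0:
        return pd.DataFrame(columns=cols)

    sos = sps.butter(4, [11.0, 15.0], btype="bandpass", fs=fs, output="sos")
    nrem = hypnogram.states == "N"
    n_per = int(round(hypnogram.epoch_s * fs))
    if not nrem.any():
        return pd.DataFrame(columns=cols)
    # background sigma RMS over (a sample of) NREM epochs, pre-insertion
    idx = np.flatnonzero(nrem)[:360]
    segs = np.concatenate([eeg[i * n_per:(i + 1) * n_per] for i in idx])
    bg_rms = float(np.sqrt(np.mean(sps.sosfiltfilt(sos, segs) ** 2)))
    if bg_rms == 0:
        bg_rms = 1e-12

    # NREM bouts as sample intervals
    change = np.flatnonzero(nrem[1:] != nrem[:-1]) + 1
    edges = np.concatenate([[0], change, [len(nrem)]])
    n_win = int(round(0.8 * fs))
    mean_d, sd_d = effects.spindle_duration_s
    lo_d, hi_d = effects.spindle_duration_bounds
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        if not nrem[a]:
            continue
        bout_s = (b - a) * hypnogram.epoch_s
        count = rng.poisson(effects.spindle_rate * bout_s / 60.0)
        if count == 0:
            continue
        starts = np.sort(rng.uniform(0.0, bout_s, size=count))
        durations = np.clip(rng.normal(mean_d, sd_d, size=count), lo_d, hi_d)
        last_end = -np.inf
        for st, dur in zip(starts, durations):
            if st <= last_end + 0.2:      # keep planted events separated
                continue
            truncated = False
            if st + dur > bout_s:
                dur = bout_s - st
                truncated = True
                if dur < lo_d:
                    continue
            t0 = a * hypnogram.epoch_s + st
            i0 = int(round(t0 * fs))
            n_s = int(round(dur * fs))
            t = np.arange(n_s) / fs
            shape = np.hanning(n_s) * np.sin(
                2 * np.pi * effects.spindle_freq_hz * t
                + rng.uniform(0, 2 * np.pi))
            amp = effects.spindle_snr * bg_rms / _peak_window_rms(shape, n_win)
            eeg[i0:i0 + n_s] += amp * shape
            rows.append({"start_s": t0, "duration_s": dur,
                         "amplitude": amp, "truncated": truncated})
            last_end = st + dur
    return pd.DataFrame(rows, columns=cols)


def synthesize_signal(hypnogram: Hypnogram, effects: EffectSpec,
                      config: CohortConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Recording, pd.DataFrame]:
    """State-conditioned EEG/EMG for one animal, with planted spindles.

    Returns the Recording (EEG1, EEG2, EMG) and the ground-truth spindle
    event table.
    """
    rng = rng or np.random.default_rng(config.seed)
    fs = config.fs
    n_per = int(round(config.epoch_s * fs))
    n_ep = hypnogram.n_epochs
    n = n_ep * n_per
    codes = np.fromiter((_IDX[s] for s in hypnogram.states), dtype=np.int8,
                        count=n_ep)

    comps = {
        "delta": _bandpassed_noise(rng, n, fs, (0.5, 4.0)),
        "theta": _bandpassed_noise(rng, n, fs, (4.0, 8.0)),
        "broad": _bandpassed_noise(rng, n, fs, (0.5, 30.0)),
    }
    white = rng.standard_normal(n)

    def mix(gain_tweak: float) -> np.ndarray:
        out = 0.1 * effects.noise_sd * white.copy()
        for name, comp in comps.items():
            gains = np.array([effects.state_gains[s][name] for s in STATES])
            g = gains[codes] * gain_tweak * effects.noise_sd
            out += (comp.reshape(n_ep, n_per) * g[:, None]).ravel()
        return out

    eeg1 = mix(1.0)
    events = _plant_spindles(eeg1, hypnogram, fs, effects, rng)
    eeg2 = 0.8 * eeg1 + 0.3 * effects.noise_sd * rng.standard_normal(n)

    nyq = fs / 2.0
    emg_noise = _bandpassed_noise(rng, n, fs, (10.0, min(100.0, 0.95 * nyq)))
    emg_gain = np.array([effects.emg_gains[s] for s in STATES])[codes]
    emg = (emg_noise.reshape(n_ep, n_per)
           * (emg_gain[:, None] * effects.noise_sd)).ravel()
    emg += 0.02 * effects.noise_sd * rng.standard_normal(n)

    rec = Recording(data=np.stack([eeg1, eeg2, emg]), fs=fs,
                    channel_names=("EEG1", "EEG2", "EMG"),
                    start_zt=hypnogram.start_zt)
    return rec, events


# ---------------------------------------------------------------------------
# Barnes maze
# ---------------------------------------------------------------------------

def simulate_maze(config: CohortConfig, effects: EffectSpec,
                  rng: np.random.Generator | None = None,
                  animals: pd.DataFrame | None = None,
                  rem_z: dict[str, float] | None = None,
                  include_probe: bool = True) -> pd.DataFrame:
    """Barnes-maze trial table for the cohort.

    ``animals``: DataFrame with animal_id/genotype/sex/feeding (generated
    from the config's groups if omitted).  ``rem_z`` optionally maps animal
    id to its standardized REM amount; a positive ``rem_latency_coupling``
    then shortens latencies of high-REM animals (negative REM-latency
    correlation).  Latencies decay exponentially over days 1-5 toward an
    asymptote, truncated to (0, 180] s (probe day 12: (0, 60] s); errors are
    Poisson with mean proportional to latency.
    """
    rng = rng or np.random.default_rng(config.seed)
    if animals is None:
        animals = cohort_roster(config)
    be = effects.behavior_effects
    base, asym = be["baseline_latency_s"], be["asymptote_latency_s"]
    rows = []
    for rec in animals.itertuples(index=False):
        k = be["decay_per_day"][(rec.genotype, rec.feeding)]
        z = (rem_z or {}).get(rec.animal_id, 0.0)
        ability = np.exp(-be["rem_latency_coupling"] * z
                         + rng.normal(0.0, be["animal_sigma"]))
        center_mean = be["center_time_mean_s"].get(
            (rec.genotype, rec.sex), be["center_time_mean_s"]["default"])
        days = [1, 2, 3, 4, 5] + ([12] if include_probe else [])
        for day in days:
            eff_day = min(day, 6)  # probe retention ~ post-training level
            mean_lat = asym + (base - asym) * np.exp(-k * (eff_day - 1))
            cap = 60.0 if day > 5 else 180.0
            for trial in ([1] if day > 5 else [1, 2]):
                lat = mean_lat * ability * np.exp(
                    rng.normal(0.0, be["latency_sigma"]))
                lat = float(np.clip(lat, 1.0, cap))
                rows.append({
                    "animal_id": rec.animal_id, "genotype": rec.genotype,
                    "sex": rec.sex, "feeding": rec.feeding,
                    "day": day, "trial": trial,
                    "primary_latency_s": lat,
                    "primary_errors": int(rng.poisson(
                        be["error_rate_per_s"] * lat)),
                    "time_in_center_s": float(rng.lognormal(
                        np.log(center_mean) - be["center_sigma"] ** 2 / 2,
                        be["center_sigma"])),
                    "freezing_s": float(rng.exponential(be["freezing_mean_s"])),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------

def cohort_roster(config: CohortConfig) -> pd.DataFrame:
    """One row per synthetic animal: id, genotype, sex, feeding."""
    rows = []
    for (genotype, sex, feeding) in config.groups:
        for i in range(config.n_per_group):
            rows.append({
                "animal_id": f"{genotype}_{sex}_{feeding}_{i + 1:02d}",
                "genotype": genotype, "sex": sex, "feeding": feeding})
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A simulated cohort: roster, ground-truth hypnograms, maze table.

    Signals are large, so they are synthesized on demand per animal with
    :meth:`synthesize`; repeated calls with the same cohort are
    bit-identical (per-animal seeds are spawned deterministically from the
    cohort seed).
    """

    config: CohortConfig
    effects: EffectSpec
    roster: pd.DataFrame
    hypnograms: dict[str, Hypnogram]
    maze_table: pd.DataFrame
    _signal_seeds: dict[str, np.random.SeedSequence]

    def synthesize(self, animal_id: str) -> tuple[Recording, pd.DataFrame]:
        hyp = self.hypnograms[animal_id]
        rng = np.random.default_rng(self._signal_seeds[animal_id])
        return synthesize_signal(hyp, self.effects, self.config, rng)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.roster["animal_id"])


def simulate_cohort(config: CohortConfig,
                    effects: EffectSpec | None = None) -> Cohort:
    """Simulate hypnograms and maze behavior for every animal in the design.

    The maze coupling uses each animal's *true* REM minutes (standardized
    across the cohort), so more REM means faster maze learning when the
    coupling is positive.
    """
    effects = effects or EffectSpec()
    roster = cohort_roster(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(roster) + 1)
    maze_seed, animal_seeds = children[-1], children[:-1]

    hypnograms: dict[str, Hypnogram] = {}
    signal_seeds: dict[str, np.random.SeedSequence] = {}
    for rec, seed in zip(roster.itertuples(index=False), animal_seeds):
        hyp_seed, sig_seed = seed.spawn(2)
        group = (rec.genotype, rec.sex, rec.feeding)
        hypnograms[rec.animal_id] = simulate_hypnogram(
            config, effects, group, rng=np.random.default_rng(hyp_seed))
        signal_seeds[rec.animal_id] = sig_seed

    rem = np.array([hypnograms[a].minutes("R") for a in roster["animal_id"]])
    sd = rem.std()
    z = (rem - rem.mean()) / sd if sd > 0 else np.zeros_like(rem)
    rem_z = dict(zip(roster["animal_id"], z))
    maze = simulate_maze(config, effects, rng=np.random.default_rng(maze_seed),
                         animals=roster, rem_z=rem_z)
    return Cohort(config=config, effects=effects, roster=roster,
                  hypnograms=hypnograms, maze_table=maze,
                  _signal_seeds=signal_seeds)
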
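"""Generator: occupancy calibration, topology, determinism, planted truth."""
import dataclasses

import numpy as np
import pytest
from scipy.optimize import curve_fit

from circasleep import (CohortConfig, EffectSpec, Hypnogram, simulate_cohort,
                        simulate_hypnogram, simulate_maze, synthesize_signal)
from circasleep import spectral, synthetic
from circasleep.errors import ConfigurationError

WT_DARK = ("WT", "F", "dark_fed")
TG_DARK = ("TG", "F", "dark_fed")
WT_LIGHT = ("WT", "F", "light_fed")


def test_config_invariants():
    with pytest.raises(ConfigurationError):
        CohortConfig(duration_h=30.0)
    with pytest.raises(ConfigurationError):
        CohortConfig(fs=250.0, epoch_s=0.003)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_per_group=0)
    with pytest.raises(ConfigurationError):
        CohortConfig(groups=(("XX", "F", "dark_fed"),))


def test_effects_invariants():
    bad = np.full((24, 3), 0.5)
    with pytest.raises(ConfigurationError, match="sum to 1"):
        EffectSpec(base_state_profile=bad)
    with pytest.raises(ConfigurationError):
        EffectSpec(spindle_rate=-1.0)


def test_epoch_count(small_config, effects, rng):
    hyp = simulate_hypnogram(small_config, effects, WT_DARK, rng=rng)
    assert hyp.n_epochs == small_config.n_epochs == 8640


def test_rem_unreachable_from_wake(small_config, effects, rng):
    hyp = simulate_hypnogram(small_config, effects, WT_DARK, rng=rng)
    s = hyp.states
    trans = set(zip(s[:-1], s[1:]))
    assert ("W", "R") not in trans
    assert ("R", "N") not in trans  # REM exits to wake in this topology
    with pytest.raises(ConfigurationError, match="REM"):
        simulate_hypnogram(small_config, effects, WT_DARK, rng=rng,
                           allowed_transitions={("W", "R"), ("W", "N")})


def test_nrem_mass_in_light_phase(small_config, effects, rng):
    hyp = simulate_hypnogram(small_config, effects, WT_DARK, rng=rng)
    zt = hyp.zt_hours()
    nrem = hyp.states == "N"
    assert (zt[nrem] < 12).mean() > 0.5


def test_zero_rem_occupancy_gives_no_rem(small_config, rng):
    prof = synthetic.default_state_profile()
    prof[:, 0] += prof[:, 2]
    prof[:, 2] = 0.0
    effects = EffectSpec(base_state_profile=prof)
    hyp = simulate_hypnogram(small_config, effects, WT_DARK, rng=rng)
    assert not (hyp.states == "R").any()


def test_occupancy_matches_configured_profile(effects):
    """Monte-Carlo: mean per-hour occupancy over many simulated days equals
    the configured profile.

    The bound is 4x the empirical SE of the mean (72 simultaneous bin/state
    comparisons; a 3-sigma per-element bound would false-alarm at the family
    level) plus 0.012 for the analytically expected relaxation lag in the
    first bin after each lights transition (the chain re-equilibrates over
    ~8 epochs after a step change in the target profile).
    """
    config = CohortConfig(n_per_group=1, duration_h=24.0, fs=100.0, seed=0)
    prof = synthetic.group_profile(effects, WT_DARK)
    n_days = 60
    occ = np.zeros((n_days, 24, 3))
    rng = np.random.default_rng(2024)
    for d in range(n_days):
        hyp = simulate_hypnogram(config, effects, WT_DARK, rng=rng)
        hours = hyp.zt_hours().astype(int)
        for j, s in enumerate(synthetic.STATES):
            sel = hyp.states == s
            occ[d, :, j] = np.bincount(hours[sel], minlength=24) / 360.0
    mean = occ.mean(axis=0)
    se = occ.std(axis=0, ddof=1) / np.sqrt(n_days)
    dev = np.abs(mean - prof)
    assert np.all(dev <= 4 * se + 0.012), \
        f"max deviation {dev.max():.4f} vs bound {(4 * se + 0.012).max():.4f}"


def test_genotype_effect_monotonicity(small_config):
    """Stronger NREM suppression never increases expected NREM minutes."""
    expected = []
    for scale in (1.0, 0.85, 0.6):
        eff = EffectSpec(genotype_effects={"nrem_scale": scale,
                                           "rem_scale": 0.75})
        prof = synthetic.group_profile(eff, TG_DARK)
        expected.append(prof[:, 1].sum() * 60.0)  # minutes/day expected
    assert expected[0] >= expected[1] >= expected[2]
    # and realized in simulation
    sims = []
    for scale in (1.0, 0.6):
        eff = EffectSpec(genotype_effects={"nrem_scale": scale,
                                           "rem_scale": 0.75})
        hyp = simulate_hypnogram(small_config, eff, TG_DARK,
                                 rng=np.random.default_rng(7))
        sims.append(hyp.minutes("N"))
    assert sims[0] > sims[1]


def test_feeding_transposition_moves_nrem_into_late_dark(effects):
    base = synthetic.group_profile(effects, WT_DARK)
    trans = synthetic.group_profile(effects, WT_LIGHT)
    span = effects.feeding_effects["transposition_span_h"]
    assert np.all(trans[:span, 1] < base[:span, 1])        # early light loses
    assert np.all(trans[24 - span:, 1] > base[24 - span:, 1])  # late dark gains
    assert np.allclose(trans.sum(axis=1), 1.0)


def test_seed_determinism():
    config = CohortConfig(n_per_group=1, duration_h=24.0, fs=100.0, seed=3,
                          groups=(WT_DARK, TG_DARK))
    c1 = simulate_cohort(config)
    c2 = simulate_cohort(config)
    a = c1.animal_ids[0]
    assert np.array_equal(c1.hypnograms[a].states, c2.hypnograms[a].states)
    assert c1.maze_table.equals(c2.maze_table)
    r1, e1 = c1.synthesize(a)
    r2, e2 = c2.synthesize(a)
    assert np.array_equal(r1.data, r2.data)
    assert e1.equals(e2)


def test_zero_spindle_rate_no_events(small_config, rng):
    effects = EffectSpec(spindle_rate=0.0)
    hyp = Hypnogram(states=np.array(["N"] * 60), epoch_s=10.0)
    _, events = synthesize_signal(hyp, effects, small_config, rng)
    assert len(events) == 0


def test_planted_count_poisson_mean():
    """One 60-s NREM interval at 2/min: mean planted count ~ 2 over seeds."""
    config = CohortConfig(n_per_group=1, duration_h=24.0, fs=100.0, seed=0)
    effects = EffectSpec(spindle_rate=2.0)
    hyp = Hypnogram(states=np.array(["N"] * 6), epoch_s=10.0)
    counts = []
    rng = np.random.default_rng(99)
    for _ in range(200):
        _, ev = synthesize_signal(hyp, effects, config, rng)
        counts.append(len(ev))
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    # slightly below 2 is expected: overlapping draws are dropped
    assert abs(mean - 2.0) <= max(3 * se, 0.25)


def test_planted_spindles_lie_within_nrem(small_config, rng):
    states = np.array((["N"] * 30 + ["W"] * 6) * 10)
    hyp = Hypnogram(states=states, epoch_s=10.0)
    effects = EffectSpec(spindle_rate=3.0)
    _, events = synthesize_signal(hyp, effects, small_config, rng)
    assert len(events) > 0
    n_per = 10.0
    for _, ev in events.iterrows():
        first = int(ev["start_s"] // n_per)
        last = int((ev["start_s"] + ev["duration_s"] - 1e-9) // n_per)
        assert all(states[first:last + 1] == "N")


def test_emg_ranks_wake_above_sleep(small_config, rng):
    states = np.array(["W"] * 60 + ["N"] * 60 + ["R"] * 60)
    hyp = Hypnogram(states=states, epoch_s=10.0)
    rec, _ = synthesize_signal(hyp, EffectSpec(), small_config, rng)
    rms = spectral.emg_rms(rec)
    w, n, r = rms[:60].mean(), rms[60:120].mean(), rms[120:].mean()
    assert w > n >= r


def test_maze_zero_decay_constant_latency(small_config):
    be = EffectSpec().behavior_effects | {
        "decay_per_day": {(g, f): 0.0 for g in ("WT", "TG")
                          for f in ("light_fed", "dark_fed")},
        "latency_sigma": 0.0, "animal_sigma": 0.0}
    effects = dataclasses.replace(EffectSpec(), behavior_effects=be)
    maze = simulate_maze(small_config, effects,
                         rng=np.random.default_rng(0), include_probe=False)
    for _, grp in maze.groupby("animal_id"):
        assert grp["primary_latency_s"].nunique() == 1


def test_maze_learning_declines(small_config):
    config = dataclasses.replace(small_config, n_per_group=20)
    maze = simulate_maze(config, EffectSpec(),
                         rng=np.random.default_rng(1), include_probe=False)
    daily = maze.groupby("day")["primary_latency_s"].mean()
    assert daily.is_monotonic_decreasing


def test_maze_caps(small_config):
    maze = simulate_maze(small_config, EffectSpec(),
                         rng=np.random.default_rng(2))
    train = maze[maze["day"] <= 5]
    probe = maze[maze["day"] > 5]
    assert ((train["primary_latency_s"] > 0)
            & (train["primary_latency_s"] <= 180.0)).all()
    assert (probe["primary_latency_s"] <= 60.0).all()
    assert (maze["primary_errors"] >= 0).all()


def test_maze_errors_correlate_with_latency(small_config):
    config = dataclasses.replace(small_config, n_per_group=10)
    maze = simulate_maze(config, EffectSpec(),
                         rng=np.random.default_rng(3), include_probe=False)
    r = np.corrcoef(maze["primary_latency_s"], maze["primary_errors"])[0, 1]
    assert r > 0.5


def test_decay_rate_recovery():
    """Curve fit on 50 simulated animals recovers the configured decay."""
    config = CohortConfig(n_per_group=50, duration_h=24.0, fs=100.0, seed=0,
                          groups=(WT_DARK,))
    effects = EffectSpec()
    k_true = effects.behavior_effects["decay_per_day"][("WT", "dark_fed")]
    maze = simulate_maze(config, effects, rng=np.random.default_rng(4),
                         include_probe=False)
    daily = maze.groupby("day")["primary_latency_s"].mean()

    def model(d, base, asym, k):
        return asym + (base - asym) * np.exp(-k * (d - 1))

    popt, _ = curve_fit(model, daily.index.to_numpy(dtype=float),
                        daily.to_numpy(), p0=(120.0, 20.0, 0.3),
                        maxfev=10000)
    assert abs(popt[2] - k_true) / k_true <= 0.20
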
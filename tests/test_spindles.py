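"""Spindle envelope and dual-threshold detection: closed forms and a
brute-force run-scanner oracle."""
import numpy as np
import pandas as pd
import pytest

from circasleep import Hypnogram, Recording, SpindleParams
from circasleep import spindles as spn
from circasleep.errors import ConfigurationError


def make_env(values, mask=None, step_s=0.2, window_s=0.8):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    return spn.SigmaEnvelope(values=values, nrem_mask=np.asarray(mask),
                             step_s=step_s, window_s=window_s)


def bruteforce_detect(env, params):
    """Explicit window-run scanner implementing the detection rules."""
    vals, mask = env.values, env.nrem_mask
    nrem = vals[mask]
    mu, sd = nrem.mean(), nrem.std()
    if sd == 0:
        return []
    thr1, thr2 = mu + params.primary_k * sd, mu + params.secondary_k * sd
    runs, cur = [], None
    for i in range(len(vals)):
        if mask[i] and vals[i] > thr1:
            cur = [i, i] if cur is None else [cur[0], i]
        else:
            if cur is not None:
                runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    kept = [r for r in runs if np.any(vals[r[0]:r[1] + 1] > thr2)]
    merged = []
    for s, e in kept:
        gap_s = (s - merged[-1][1] - 1) * env.step_s if merged else np.inf
        if gap_s < params.merge_gap_ms / 1000.0:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        dur = (e - s + 1) * env.step_s
        if params.min_duration_s <= dur <= params.max_duration_s:
            events.append((s, e))
    return events


def test_envelope_of_pure_sinusoid():
    fs, amp = 250.0, 3.7
    t = np.arange(int(fs * 120)) / fs
    x = amp * np.sin(2 * np.pi * 13.0 * t)
    rec = Recording(data=np.stack([x, x, np.zeros_like(x)]), fs=fs)
    hyp = Hypnogram(states=np.array(["N"] * 12), epoch_s=10.0)
    env = spn.sigma_envelope(rec, hyp)
    mid = env.values[5:-5]
    assert np.allclose(mid, amp / np.sqrt(2), rtol=0.02)


def test_envelope_of_zero_signal():
    rec = Recording(data=np.zeros((3, 2500)), fs=250.0)
    hyp = Hypnogram(states=np.array(["N"]), epoch_s=10.0)
    env = spn.sigma_envelope(rec, hyp)
    assert np.all(env.values == 0.0)


def test_envelope_window_count():
    fs = 250.0
    n = int(fs * 30)
    rec = Recording(data=np.zeros((3, n)), fs=fs)
    hyp = Hypnogram(states=np.array(["N"] * 3), epoch_s=10.0)
    env = spn.sigma_envelope(rec, hyp)
    n_win, n_step = int(0.8 * fs), int(0.2 * fs)
    assert len(env.values) == (n - n_win) // n_step + 1


def test_envelope_masks_non_nrem_windows():
    fs = 250.0
    rec = Recording(data=np.zeros((3, int(fs * 30))), fs=fs)
    hyp = Hypnogram(states=np.array(["N", "W", "N"]), epoch_s=10.0)
    env = spn.sigma_envelope(rec, hyp)
    centers = env.centers_s
    inside_wake = (centers > 10.4) & (centers < 19.6)
    assert not env.nrem_mask[inside_wake].any()
    fully_nrem = centers < 9.5
    assert env.nrem_mask[fully_nrem].all()


def test_short_recording_rejected():
    rec = Recording(data=np.zeros((3, 100)), fs=250.0)
    hyp = Hypnogram(states=np.array(["N"]), epoch_s=10.0)
    with pytest.raises(ConfigurationError):
        spn.sigma_envelope(rec, hyp)


def test_planted_burst_duration_quantization(rng):
    """A 1.0-s high burst on a noisy floor: one event within one step."""
    n = 600
    vals = 1.0 + 0.01 * rng.standard_normal(n)
    vals[300:305] = 10.0  # 5 windows x 0.2 s = 1.0 s
    env = make_env(vals)
    events = spn.detect_spindles(env)
    assert len(events) == 1
    assert abs(events["duration_s"].iloc[0] - 1.0) <= 0.2 + 1e-9


def test_burst_below_secondary_is_vetoed(rng):
    vals = 1.0 + 0.1 * rng.standard_normal(600)
    mu, sd = vals.mean(), vals.std()
    lift = mu + 1.2 * sd  # above primary (0.5 SD), below secondary (2 SD)
    vals2 = vals.copy()
    vals2[100:110] = lift
    env = make_env(vals2)
    params = SpindleParams()
    mu2, sd2 = vals2.mean(), vals2.std()
    assert lift > mu2 + params.primary_k * sd2
    assert lift < mu2 + params.secondary_k * sd2
    got = spn.detect_spindles(env, params)
    starts_in_burst = ((got["start_s"] >= 100 * 0.2 - 0.5)
                       & (got["start_s"] <= 110 * 0.2 + 0.5))
    assert not starts_in_burst.any()


def test_degenerate_envelope_flagged():
    env = make_env(np.ones(50))
    with pytest.warns(UserWarning, match="degenerate"):
        events = spn.detect_spindles(env)
    assert len(events) == 0


def test_oracle_equivalence_random_envelopes(rng):
    params = SpindleParams()
    for _ in range(200):
        n = int(rng.integers(30, 400))
        vals = np.abs(rng.standard_normal(n))
        vals[rng.random(n) < 0.05] += rng.uniform(2, 8)
        mask = rng.random(n) < 0.8
        if not mask.any():
            mask[0] = True
        env = make_env(vals, mask)
        if vals[mask].std() == 0:
            continue
        got = spn.detect_spindles(env, params)
        want = bruteforce_detect(env, params)
        assert len(got) == len(want)
        for (_, row), (s, e) in zip(got.iterrows(), want):
            assert row["start_s"] == pytest.approx(env.centers_s[s] - 0.1)
            assert row["n_windows"] == e - s + 1


def test_amplitude_scale_equivariance(rng):
    vals = np.abs(rng.standard_normal(500)) + 0.5
    vals[100:106] = 8.0
    vals[300:307] = 9.0
    env1 = make_env(vals)
    env2 = make_env(vals * 12.5)
    e1 = spn.detect_spindles(env1)
    e2 = spn.detect_spindles(env2)
    assert len(e1) == len(e2) >= 1
    assert np.allclose(e1["duration_s"], e2["duration_s"])
    assert np.allclose(e2["rms_amplitude"], 12.5 * e1["rms_amplitude"])
    assert np.allclose(e2["peak_envelope"], 12.5 * e1["peak_envelope"])


def test_merge_gap():
    vals = np.full(100, 1.0)
    vals[:50] += 0.01 * np.sin(np.arange(50))  # give sd > 0
    vals[60:63] = 5.0
    vals[64:67] = 5.0  # one-window gap = 0.2 s, not < merge_gap
    env = make_env(vals)
    events = spn.detect_spindles(env)
    assert len(events) == 2
    params = SpindleParams(merge_gap_ms=300.0)
    events2 = spn.detect_spindles(env, params)
    assert len(events2) == 1


def test_duration_filter():
    vals = np.full(200, 1.0)
    vals[:50] += 0.01 * np.sin(np.arange(50))
    vals[100:120] = 5.0  # 4.0 s run, above max_duration 3.0
    vals[150:151] = 5.0  # 0.2 s run, below min_duration 0.5
    env = make_env(vals)
    assert len(spn.detect_spindles(env)) == 0


def test_summary_arithmetic(make_hypnogram):
    hyp = Hypnogram(states=np.array(["N"] * 1800), epoch_s=10.0)  # 300 min
    events = pd.DataFrame({"start_s": np.arange(30.0),
                           "duration_s": np.ones(30),
                           "peak_envelope": np.ones(30),
                           "rms_amplitude": np.full(30, 2.0),
                           "n_windows": np.full(30, 5)})
    out = spn.spindle_summary(events, hyp)
    assert out["density_per_min_nrem"] == pytest.approx(0.1)
    assert out["mean_duration_s"] == pytest.approx(1.0)
    assert out["mean_rms_amplitude"] == pytest.approx(2.0)
    empty = pd.DataFrame(columns=events.columns)
    out0 = spn.spindle_summary(empty, hyp)
    assert out0["n_spindles"] == 0 and out0["density_per_min_nrem"] == 0.0


def test_zero_nrem_density_undefined():
    hyp = Hypnogram(states=np.array(["W"] * 10), epoch_s=10.0)
    empty = pd.DataFrame(columns=["start_s", "duration_s", "peak_envelope",
                                  "rms_amplitude", "n_windows"])
    with pytest.warns(UserWarning, match="undefined"):
        out = spn.spindle_summary(empty, hyp)
    assert np.isnan(out["density_per_min_nrem"])


def test_params_validation():
    with pytest.raises(ConfigurationError):
        SpindleParams(window_ms=800, step_ms=300)
    with pytest.raises(ConfigurationError):
        SpindleParams(primary_k=2.0, secondary_k=0.5)
    with pytest.raises(ConfigurationError):
        SpindleParams(min_duration_s=3.0, max_duration_s=0.5)
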
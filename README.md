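# circasleep

Analysis toolkit for sleep EEG/EMG, circadian sleep rhythms and spatial
learning in mouse cohorts under phase-restricted feeding — the 2×2×2 design
(genotype × sex × feeding phase) in which food access is limited to the 12-h
light phase (mistimed for a nocturnal animal) or the 12-h dark phase, sleep
is recorded for 48 h under 12:12 LD, and spatial memory is assayed in a
Barnes maze.  It is aimed at sleep/chronobiology labs who score rodent
EEG/EMG in 10-s epochs and want a reproducible, scriptable path from raw
recordings to group statistics.

Because real recordings of this kind are rarely shareable, the package
includes a first-class synthetic-cohort generator with known ground truth
(hypnograms, planted spindles, maze learning curves), so that every stage of
the pipeline can be validated by recovery experiments.

## What it computes

* **Vigilance-state scoring** — semi-supervised: an expert labels ~8% of a
  recording's 10-s epochs; a per-recording classifier (7 features: the five
  band fractions δ 0.5–4, θ 4–8, α 8–11, σ 11–15, β 15–30 Hz, log total
  power, log EMG RMS) scores the rest into Wake/NREM/REM.
* **Sleep architecture** — state minutes in 3/12/24-h ZT bins, bouts
  (maximal same-state runs), state changes, brief arousals (flanked wake
  bouts ≤ 2 epochs), and the proportion of each state in its expected phase
  (wake in dark, NREM/REM in light).
* **Circular rhythm statistics** — each epoch of a state contributes a unit
  vector at angle θ = 2π·ZT/24; the normalized resultant
  R·e^{iφ} = (1/n)Σe^{iθ} gives the state's peak time (φ·24/2π) and its
  *relative amplitude* R ∈ [0, 1] (0 = arrhythmic, 1 = fully consolidated).
* **Sleep spindles** — sigma-band (11–15 Hz) RMS envelope over an 800-ms
  window stepped by 200 ms; events are runs above μ + 0.5σ of the NREM
  envelope (primary threshold) containing at least one window above
  μ + 2.0σ (secondary threshold), merged and duration-filtered.  Reported
  per animal: count/24 h, mean duration, density per NREM minute, RMS
  amplitude.
* **Relative PSD** — per-epoch Welch spectra (2-s Hann segments, 50%
  overlap), normalized to each epoch's total 0.5–30 Hz power and averaged
  per state.
* **Barnes maze** — per-day mean primary latency and primary errors,
  trapezoidal AUC over training days as the overall learning score,
  time-in-center and freezing as anxiety measures.
* **Statistics** — 2-/3-way Type-III ANOVA (sum-to-zero coding) for
  genotype/sex/feeding effects, pooled two-tailed t-tests for post-hoc
  pairs, and Pearson correlations between sleep and cognitive measures with
  Bonferroni correction.

## Worked example

```python
import numpy as np
from circasleep import (CohortConfig, EffectSpec, SleepScorer,
                        simulate_cohort, relative_amplitude)
from circasleep import scoring, spectral

config = CohortConfig(n_per_group=1, duration_h=24.0, fs=100.0, seed=7)
cohort = simulate_cohort(config, EffectSpec())

animal = "WT_F_dark_fed_01"
recording, _ = cohort.synthesize(animal)      # EEG1/EEG2/EMG signals
truth = cohort.hypnograms[animal]             # ground-truth hypnogram

features = spectral.extract_features(recording)
labels = scoring.subsample_labels(truth, 0.08, rng=np.random.default_rng(0))
scored = SleepScorer(seed=0).fit(features, labels).predict(features)

held_out = np.array(sorted(labels))
print(f"held-out accuracy : {scoring.accuracy(truth, scored, exclude=held_out):.3f}")
print(f"NREM minutes      : {scored.minutes('N'):.1f}")
print(f"NREM rel. amplitude: {relative_amplitude(scored, 'N'):.3f}")
```

Output:

```
held-out accuracy : 1.000
NREM minutes      : 554.8
NREM rel. amplitude: 0.330
```

The scorer recovers all held-out epochs from an 8% label fraction on this
artifact-free synthetic recording; the dark-fed wild-type animal sleeps
~555 NREM minutes per day, and the NREM rhythm's relative amplitude of
~0.33 reflects normal light-phase consolidation (a light-fed animal under
the default transposition effect comes out lower).

The same workflow is available from the shell:

```bash
circasleep simulate --outdir cohort --seed 7 --n-per-group 1 --fs 100
circasleep score cohort/WT_F_dark_fed_01.edf cohort/WT_F_dark_fed_01.labels.csv \
    --out scored.csv
circasleep rhythm scored.csv --out rhythm.csv
circasleep run-all --seed 7 --outdir results/full_run
```

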
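# Methods

This note documents the models and procedures implemented in `circasleep`,
the choices made where conventions vary, and what the synthetic-data
validation does and does not establish.

## Study design conventions

Time of day is expressed in zeitgeber time (ZT): ZT0 = lights on, ZT12 =
lights off under a 12:12 light–dark cycle.  The light schedule travels in a
YAML sidecar next to each EDF rather than being inferred from the EDF start
clock, which avoids acquisition-clock ambiguity.  Recordings are epoched
into 10-s epochs (half-open sample intervals, 0-based, trailing partial
epoch dropped), the standard granularity for rodent polysomnography.  The
cohort design is 2×2×2: genotype (WT vs transgenic "TG"), sex, and feeding
phase (light-fed = mistimed, dark-fed = correctly timed), with 48-h
recordings at 250 Hz (2 EEG + 1 EMG channels) as the default conditions.

## Synthetic cohort generator

The generator exists so that every downstream stage can be validated
against known ground truth; it is deliberately phenomenological, not a
neural-mass model.

**Hypnograms.**  States follow a per-epoch persistence chain over
{W, N, R}: each epoch the animal keeps its state with probability
p_s (defaults W 0.92, N 0.90, R 0.85, i.e. geometric dwells of ~125/100/67 s,
in the range of adult-mouse bout durations), otherwise it redraws from a
bin-specific distribution q.  Transitions obey the rodent topology W↔N,
N→R, R→W; a redraw that would make an illegal move is redirected (from W,
an R draw becomes N; from R, an N draw becomes W).  Given a target hourly
occupancy profile π, q is solved per ZT bin in closed form from flow
balance — with a = π_W(1−p_W), b = π_N(1−p_N), c = π_R(1−p_R):

    q_R = c/(b+c),   q_W = (a − c(1−q_R))/(a+b),   q_N = 1 − q_W − q_R,

so the chain's stationary occupancy equals π exactly.  The solution is
feasible iff b(b+c) ≥ ac; in very wake-dominant bins (e.g. the suppressed
sleep of the TG genotype in the dark phase) the wake persistence for that
bin is raised until the balance is solvable, which preserves occupancy at
the cost of longer wake bouts.  After a step change in π (the lights
transitions) the marginal re-equilibrates over ~8 epochs, so bin-average
occupancy in the first bin after a transition deviates by ≲0.012; this is
the only systematic deviation and the calibration test accounts for it.

The default profile puts the animal mostly asleep in the light phase
(W/N/R = 0.35/0.55/0.10 per hour) and mostly awake in the dark
(0.78/0.19/0.03) — typical fractions for C57-background mice.  Group
effects act on the profile: the TG genotype scales NREM and REM occupancy
(defaults ×0.85 and ×0.75, wake absorbing the difference), and light-fed
groups have a configurable fraction (default 0.35) of NREM occupancy moved
from the first 3 h of the light phase to the last 3 h of the dark phase —
the "transposition" signature of mistimed feeding.  The literature reports
such contrasts only as ANOVA outcomes on real animals, so the magnitudes
are free parameters; the defaults were chosen once as qualitatively
realistic and are not fitted to anything.

**Signals.**  EEG is a state-gain mixture of three independent band-limited
noise components (delta 0.5–4, theta 4–8, broadband 0.5–30 Hz) plus a small
white floor, in arbitrary units with ~unit background scale (relative
metrics make physical calibration unnecessary).  NREM is delta-dominant,
REM theta-dominant, wake mixed; the EMG channel is 10–100 Hz noise with
amplitude Wake > NREM > REM (atonia).  Gains switch at epoch boundaries,
which introduces spectral edge artifacts no larger than those of real
state transitions.

**Spindles.**  Hann-windowed 12.5-Hz sinusoidal bursts are planted at
Poisson times within NREM bouts, duration ~N(1.0, 0.3) s clipped to
[0.5, 2.0] s, at a default density of 3/min of NREM (automated detectors in
mice typically report 2–6/min).  Burst amplitude is set so the burst's peak
800-ms windowed RMS equals a configurable multiple (the *envelope SNR*,
default 5) of the background sigma-band RMS measured from the pre-insertion
signal.  Bursts that would overrun their NREM bout are truncated and
flagged; overlapping draws are dropped, so realized density is marginally
below nominal.  Every planted event is recorded as ground truth.

**Barnes maze.**  Trial latency is lognormal noise around an exponentially
decaying mean, asym + (base − asym)·e^{−k(day−1)} (base 140 s, asymptote
15 s), truncated to (0, 180] s (probe day: (0, 60] s); k depends on
genotype × feeding (defaults 0.55/0.35/0.35/0.20 for WT-dark/WT-light/
TG-dark/TG-light: all groups learn, TG and mistimed feeding learn slower).
Errors are Poisson with mean proportional to latency (0.08/s).
Time-in-center is lognormal with a higher mean for TG females (18 s vs
6 s), mirroring the reduced-anxiety phenotype.  A REM→latency coupling
(default 0.35) multiplies an animal's latencies by e^{−0.35·z}, where z is
its standardized true REM minutes — encoding the REM–cognition association
the correlation layer is meant to detect.

## Spectral estimation

Per-epoch PSDs are Welch estimates with 2-s Hann segments and 50% overlap
(0.5-Hz resolution, matching the delta lower edge; the estimator is a
package choice — the upstream convention is unspecified).  Band powers are
rectangular sums of PSD·df over half-open intervals, so the five bands tile
0.5–30 Hz exactly and fractions sum to 1.  Relative PSD normalizes each
epoch's spectrum to its own total power *before* state-averaging (this
de-weights high-power artifact epochs); normalizing the state mean instead
is available via `per_epoch_normalization=False`.  EMG activity is the RMS
of the 10–100 Hz band-passed EMG per epoch (upper edge capped below
Nyquist).  PSDs are computed across the whole recording with an optional
light/dark phase filter.

## Vigilance-state scoring

One classifier per recording, mirroring per-file expert calibration: the
expert labels ~8% of epochs; a small random forest (100 trees, seeded;
regularized LDA available) on the 7-dim feature vector scores the rest.
Unscorable epochs (NaNs) are imputed from the nearest scored neighbor and
flagged.  Temporal smoothing (3-epoch majority) exists but is off by
default because it alters bout statistics.  Fitting is deterministic given
(features, labels, seed).  Validation is recovery against synthetic ground
truth — held-out accuracy ≥0.90 and REM recall ≥0.8 at the generator's
default SNR, with a shuffled-label control collapsing to the class prior.
This establishes that the pipeline recovers state structure of the kind the
generator produces; real recordings carry artifacts, state-transition
ambiguity and inter-scorer disagreement the generator does not emulate, so
recovery rates on real data will be lower.

## Sleep architecture

Metrics are computed from the hypnogram alone.  A bout is a maximal
same-state run; a brief arousal is a wake bout of ≤2 epochs (≤20 s, the
conventional rodent range; threshold configurable) flanked by sleep on both
sides — EMG confirmation is not required.  Bouts are assigned to the 3-h ZT
bin containing their first epoch.  For 48-h recordings, matching ZT bins of
the two days are averaged by default (a concatenated mode exists).
Expected phases for the correct-phase proportion: wake in ZT12–24, NREM and
REM in ZT0–12.

## Circular rhythm statistics

Epoch midpoints (not starts — negligible at 10 s but stated for
reproducibility) map to angles θ = 2π·ZT/24; each epoch of a state
contributes a unit vector, all cycles of a multi-day recording pooled.  The
normalized resultant's direction is the peak ZT and its modulus the
relative amplitude.  No Rayleigh test is attached: under an entrained LD
design the period is fixed at 24 h and the vector is used descriptively.

## Spindle detection

Zero-phase 4th-order Butterworth band-pass to 11–15 Hz, then RMS over
800-ms windows stepped by 200 ms; windows overlapping any non-NREM epoch
are masked out.  Thresholds are μ + 0.5σ (primary) and μ + 2.0σ (secondary)
of the recording's NREM-only envelope — computed on the envelope as it is,
spindles included, as any analysis of real data necessarily does.
Candidate events are maximal runs of supra-primary windows; a run is kept
only if one window exceeds the secondary threshold (the secondary acts as a
veto, the primary defines the extent).  Events closer than 200 ms merge;
durations outside [0.5, 3.0] s are discarded (bounds conventional for
rodent spindles and config-exposed, as the upstream method does not print
them).  Each window's value is assigned to its *centre* and an event's
extent is one step per window (start = first centre − step/2), so durations
are quantized to 200 ms and a burst elevating n windows reports n·0.2 s —
the convention under which planted 1-s bursts are recovered to within one
step.  Both thresholds are relative, making counts and durations invariant
to signal scale.

## Statistics

Type-III sums of squares with sum-to-zero coding (via statsmodels OLS),
appropriate for the unequal cell sizes of real cohorts and equal to the
classical sequential SS in balanced designs (the tests verify this
equivalence to 1e-8).  Time-binned responses are treated as between-bin
factors on per-bin summaries, not as a within-subject repeated-measures
model — a documented simplification.  Post-hoc pairs use the pooled
two-tailed Student's t (degenerate zero-variance inputs: t = 0, p = 1 for
equal means, infinite t flagged otherwise).  The sleep–cognition family
uses Pearson r with Bonferroni adjustment p_adj = min(1, m·p), where m
counts the pairs actually tested (zero-variance or under-sampled pairs are
skipped with a warning and excluded from m).

## Problem sizes used in validation

The package's own test and acceptance runs use scaled-down cohorts chosen
to exercise every code path with stable statistics: 24-h recordings at
100–250 Hz, 1–2 animals per group (16 animals for the effect-propagation
check), 120 NREM-minutes fixtures with ~360 planted spindles for detector
recovery, 10⁴ random hypnograms for the architecture oracles, and 10³
random envelopes for the detector/oracle equivalence.  The generator's
*defaults* remain the full study conditions (48 h, 250 Hz, 8 groups).

## Known limitations

* The synthetic EEG has no artifacts, no 1/f background, no spindle
  frequency drift and no slow-oscillation coupling; detector and scorer
  performance on it bound what the same code does on real data from above.
* The equivalence of this scoring implementation to any specific
  laboratory's in-house scorer cannot be established from recovery
  experiments alone.
* Ingest/simulate parity is exact up to 16-bit EDF quantization of the
  written signals (metrics agree to ~0.1%, not bit-for-bit).
* No repeated-measures error structure in the ANOVA layer; no mixed
  models.
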
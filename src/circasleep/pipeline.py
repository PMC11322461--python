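"""End-to-end orchestration: cohort -> scoring -> metrics -> stats bundle.

Stages mirror the analysis workflow: simulate (or ingest) recordings,
extract per-epoch features, fit a per-animal scorer on a small labeled
fraction, score the rest, then compute sleep-architecture, rhythm, spindle,
relative-PSD and Barnes-maze metrics, and finally the group-comparison and
sleep-cognition correlation layer.  Every run writes tidy CSVs plus a
manifest recording the seed, the config snapshot, warnings and a SHA-256
hash of each output, so any number in the bundle can be regenerated.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture, behavior, rhythm, spectral, spindles, stats
from .errors import ConfigurationError, StageError
from .io import (Hypnogram, Recording, read_labels_csv, read_recording,
                 write_hypnogram_csv, write_labels_csv, write_recording)
from .scoring import SleepScorer, accuracy, subsample_labels
from .spindles import SpindleParams
from .synthetic import Cohort, CohortConfig, EffectSpec, simulate_cohort

log = logging.getLogger("circasleep.pipeline")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; the seed is recorded in the manifest."""

    outdir: str | Path = "circasleep_run"
    mode: str = "simulate"                  # or "ingest"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    spindle_params: SpindleParams = field(default_factory=SpindleParams)
    label_fraction: float = 0.08
    scorer_kwargs: dict = field(default_factory=dict)
    smooth: bool = False
    write_edf: bool = False                 # simulate mode: also write EDFs
    # ingest mode inputs
    roster_csv: str | None = None           # animal_id,genotype,sex,feeding
    edf_dir: str | None = None              # <animal_id>.edf (+ .yaml sidecar)
    labels_dir: str | None = None           # <animal_id>.labels.csv
    maze_csv: str | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _animal_metrics(animal_id: str, recording: Recording, hyp_scored: Hypnogram,
                    psd: np.ndarray, freqs: np.ndarray,
                    params: SpindleParams) -> dict:
    arch = architecture.architecture_summary(hyp_scored, animal=animal_id)
    rhy = rhythm.rhythm_table(hyp_scored, animal=animal_id)
    env = spindles.sigma_envelope(recording, hyp_scored, params)
    events = spindles.detect_spindles(env, params)
    spin = spindles.spindle_summary(events, hyp_scored, animal=animal_id)
    rel = spectral.relative_psd_table(psd, freqs, hyp_scored, animal=animal_id)
    return {"architecture": arch, "rhythm": rhy, "spindle_events": events,
            "spindle_summary": spin, "relative_psd": rel}


def _sleep_metric_row(animal_id: str, metrics: dict) -> dict:
    arch = metrics["architecture"].iloc[0]
    rhy = metrics["rhythm"].set_index("state")
    rel = metrics["relative_psd"]
    row = {
        "animal_id": animal_id,
        "nrem_minutes": arch["N_minutes"],
        "rem_minutes": arch["R_minutes"],
        "wake_minutes": arch["W_minutes"],
        "nrem_relative_amplitude": (rhy.loc["N", "vector_length"]
                                    if "N" in rhy.index else np.nan),
        "rem_relative_amplitude": (rhy.loc["R", "vector_length"]
                                   if "R" in rhy.index else np.nan),
        "spindle_density": metrics["spindle_summary"]["density_per_min_nrem"],
    }
    rem_psd = rel[rel["state"] == "R"]
    for band, (lo, hi) in (("alpha", (8.0, 11.0)), ("sigma", (11.0, 15.0))):
        if len(rem_psd):
            m = ((rem_psd["frequency_hz"] >= lo)
                 & (rem_psd["frequency_hz"] < hi))
            row[f"rem_{band}_relative_power"] = float(
                rem_psd.loc[m, "relative_power"].sum())
        else:
            row[f"rem_{band}_relative_power"] = np.nan
    return row


def _load_ingest(config: RunConfig):
    roster = pd.read_csv(config.roster_csv)
    hypnotruth: dict[str, dict[int, str]] = {}
    recordings: dict[str, Path] = {}
    for animal_id in roster["animal_id"]:
        recordings[animal_id] = Path(config.edf_dir) / f"{animal_id}.edf"
        label_path = Path(config.labels_dir) / f"{animal_id}.labels.csv"
        hypnotruth[animal_id] = read_labels_csv(label_path)
    maze = pd.read_csv(config.maze_csv)
    return roster, recordings, hypnotruth, maze


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Run every stage and write the results bundle; returns results in
    memory plus the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "mode": config.mode,
                      "warnings": [], "files": {}}
    collected: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        results = _run_stages(config, outdir, manifest)
        collected = [str(w.message) for w in caught]
    manifest["warnings"] = collected

    cfg_snapshot = dataclasses.asdict(config.cohort) | {
        "label_fraction": config.label_fraction, "mode": config.mode}
    cfg_snapshot["groups"] = [list(g) for g in cfg_snapshot["groups"]]
    manifest["config"] = cfg_snapshot

    for name, df in results["tables"].items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["files"][path.name] = _sha256(path)
    for name, path in results.get("extra_files", {}).items():
        manifest["files"][name] = _sha256(Path(path))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def _run_stages(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    cohort: Cohort | None = None
    extra_files: dict[str, Path] = {}

    if config.mode == "simulate":
        log.info("stage simulate: %d animals",
                 len(config.cohort.groups) * config.cohort.n_per_group)
        try:
            cohort = simulate_cohort(
                dataclasses.replace(config.cohort, seed=config.seed),
                config.effects)
        except Exception as exc:
            raise StageError("simulate", None, str(exc)) from exc
        roster = cohort.roster
        maze = cohort.maze_table
    elif config.mode == "ingest":
        try:
            roster, rec_paths, label_map, maze = _load_ingest(config)
        except Exception as exc:
            raise StageError("ingest", None, str(exc)) from exc
    else:
        raise StageError("configure", None, f"unknown mode {config.mode!r}")

    arch_rows, rhythm_rows, spin_rows, event_rows, psd_rows = [], [], [], [], []
    sleep_rows, scoring_rows = [], []
    label_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7]))

    for i, rec_meta in enumerate(roster.itertuples(index=False)):
        animal_id = rec_meta.animal_id
        log.info("animal %s (%d/%d)", animal_id, i + 1, len(roster))
        stage = "features"
        try:
            if config.mode == "simulate":
                recording, _events = cohort.synthesize(animal_id)
                truth = cohort.hypnograms[animal_id]
                labels = subsample_labels(truth, config.label_fraction,
                                          rng=label_rng)
                if config.write_edf:
                    edf = outdir / f"{animal_id}.edf"
                    write_recording(recording, edf)
                    extra_files[edf.name] = edf
                    lab = outdir / f"{animal_id}.labels.csv"
                    write_labels_csv(labels, lab)
                    extra_files[lab.name] = lab
                    truth_csv = outdir / f"{animal_id}.hypnogram_truth.csv"
                    write_hypnogram_csv(truth, truth_csv)
                    extra_files[truth_csv.name] = truth_csv
            else:
                recording = read_recording(rec_paths[animal_id])
                truth = None
                labels = label_map[animal_id]

            epoch_s = config.cohort.epoch_s
            features = spectral.extract_features(recording, epoch_s=epoch_s)
            freqs, psd = spectral.epoch_spectra(recording, epoch_s=epoch_s)

            stage = "score"
            scorer = SleepScorer(seed=config.seed, smooth=config.smooth,
                                 **config.scorer_kwargs)
            scorer.fit(features, labels)
            scored = scorer.predict(features, epoch_s=epoch_s,
                                    start_zt=recording.start_zt)
            srow = {"animal_id": animal_id,
                    "training_fraction": scorer.training_fraction_,
                    "in_sample_accuracy": scorer.in_sample_accuracy_}
            if truth is not None:
                srow["holdout_accuracy"] = accuracy(
                    truth, scored, exclude=np.array(sorted(labels)))
            scoring_rows.append(srow)

            stage = "metrics"
            metrics = _animal_metrics(animal_id, recording, scored,
                                      psd, freqs, config.spindle_params)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, animal_id, str(exc)) from exc

        arch_rows.append(metrics["architecture"])
        rhythm_rows.append(metrics["rhythm"])
        spin_rows.append(metrics["spindle_summary"])
        ev = metrics["spindle_events"].copy()
        ev.insert(0, "animal", animal_id)
        event_rows.append(ev)
        psd_rows.append(metrics["relative_psd"])
        sleep_rows.append(_sleep_metric_row(animal_id, metrics))
        del recording, features, psd

    try:
        daily = behavior.daily_means(maze)
        cog = behavior.behavior_summary(maze)
    except Exception as exc:
        raise StageError("behavior", None, str(exc)) from exc

    sleep_df = pd.DataFrame(sleep_rows).set_index("animal_id")
    merged = roster.merge(sleep_df.reset_index(), on="animal_id")

    try:
        factors = [f for f in ("genotype", "sex", "feeding")
                   if merged[f].nunique() > 1]
        anova_tables = []
        for response in ("nrem_minutes", "rem_minutes", "wake_minutes"):
            try:
                t = stats.factorial_anova(merged, response, factors)
            except ConfigurationError as exc:
                warnings.warn(f"ANOVA on {response} skipped: {exc}")
                continue
            t.insert(0, "response", response)
            anova_tables.append(t)
        anova = (pd.concat(anova_tables, ignore_index=True) if anova_tables
                 else pd.DataFrame(columns=["response", "term", "sum_sq",
                                            "df", "F", "p"]))
        try:
            pairwise = stats.pairwise_t_table(merged, "nrem_minutes",
                                              "genotype")
        except ConfigurationError as exc:
            warnings.warn(f"pairwise t-tests skipped: {exc}")
            pairwise = pd.DataFrame(columns=["contrast", "t", "p",
                                             "n_a", "n_b"])
        cog_idx = cog.set_index("animal_id")
        corr = stats.correlation_matrix(sleep_df, cog_idx)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", None, str(exc)) from exc

    tables = {
        "architecture": pd.concat(arch_rows, ignore_index=True),
        "rhythm": pd.concat(rhythm_rows, ignore_index=True),
        "spindle_summary": pd.DataFrame(spin_rows),
        "spindle_events": pd.concat(event_rows, ignore_index=True),
        "relative_psd": pd.concat(psd_rows, ignore_index=True),
        "scoring": pd.DataFrame(scoring_rows),
        "sleep_metrics": merged,
        "behavior_daily": daily,
        "behavior_summary": cog,
        "anova_results": anova,
        "pairwise": pairwise,
        "correlations": corr,
        "maze_trials": maze,
    }
    return {"tables": tables, "extra_files": extra_files,
            "cohort": cohort}
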
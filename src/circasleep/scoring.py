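"""Semi-supervised vigilance-state scoring.

One classifier per recording: an expert labels a small fraction of epochs
(~8% in the workflow this package supports), a discriminative model is
trained on 7 per-epoch features (five band fractions, log total power, log
EMG RMS), and the remaining epochs are classified into W/N/R.  The model
only ever predicts states present in its training labels.

The classifier family is configurable (small random forest by default, or
regularized linear discriminant); both are seedable and deterministic
given (features, labels, seed).  Temporal smoothing (3-epoch majority
filter) is off by default since it alters bout statistics.
"""
from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import Hypnogram, STATES
from .spectral import FEATURE_COLUMNS


def subsample_labels(hyp: Hypnogram, fraction: float = 0.08,
                     rng: np.random.Generator | int | None = None
                     ) -> dict[int, str]:
    """Uniformly sample a fraction of epochs as 'human' labels."""
    if not 0 < fraction <= 1:
        raise ConfigurationError("label fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    n = max(1, int(round(fraction * hyp.n_epochs)))
    idx = rng.choice(hyp.n_epochs, size=n, replace=False)
    return {int(i): str(hyp.states[i]) for i in idx}


class SleepScorer:
    """Per-recording epoch classifier with a scikit-learn backend."""

    def __init__(self, classifier: str = "random_forest", seed: int = 0,
                 smooth: bool = False, n_estimators: int = 100):
        if classifier not in ("random_forest", "lda"):
            raise ConfigurationError(f"unknown classifier {classifier!r}")
        self.classifier = classifier
        self.seed = seed
        self.smooth = smooth
        self.n_estimators = n_estimators
        self._clf = None
        self.classes_: list[str] = []
        self.training_fraction_: float = float("nan")
        self.in_sample_accuracy_: float = float("nan")

    def _make(self):
        if self.classifier == "random_forest":
            from sklearn.ensemble import RandomForestClassifier
            return RandomForestClassifier(n_estimators=self.n_estimators,
                                          random_state=self.seed)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")

    def fit(self, features: pd.DataFrame,
            labels: Mapping[int, str]) -> "SleepScorer":
        if not labels:
            raise ConfigurationError("no training labels")
        idx = np.array(sorted(labels))
        if idx.min() < 0 or idx.max() >= len(features):
            raise ConfigurationError("label epoch index out of range")
        y = np.array([labels[i] for i in idx])
        bad = set(y) - set(STATES)
        if bad:
            raise ConfigurationError(f"unknown label states {sorted(bad)}")
        if "unscorable" in features.columns:
            ok = ~features["unscorable"].to_numpy()[idx]
            idx, y = idx[ok], y[ok]
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ConfigurationError(
                "training labels contain a single state; cannot discriminate")
        counts = pd.Series(y).value_counts()
        if (counts < 5).any():
            warnings.warn(f"fewer than 5 labeled epochs for some states: "
                          f"{counts.to_dict()}")
        X = features.iloc[idx][FEATURE_COLUMNS].to_numpy()
        self._clf = self._make()
        self._clf.fit(X, y)
        self.classes_ = classes
        self.training_fraction_ = len(idx) / len(features)
        self.in_sample_accuracy_ = float(np.mean(self._clf.predict(X) == y))
        return self

    def predict(self, features: pd.DataFrame, epoch_s: float = 10.0,
                start_zt: float = 0.0) -> Hypnogram:
        if self._clf is None:
            raise ConfigurationError("scorer is not fitted")
        X = features[FEATURE_COLUMNS].to_numpy()
        pred = self._clf.predict(X).astype("<U1")
        if "unscorable" in features.columns:
            bad = features["unscorable"].to_numpy()
            if bad.any():
                pred = _impute_nearest(pred, bad)
                warnings.warn(f"{int(bad.sum())} unscorable epochs imputed "
                              "from nearest scored neighbor")
        if self.smooth:
            pred = _majority3(pred)
        return Hypnogram(states=pred, epoch_s=epoch_s, start_zt=start_zt,
                         labels_source="classifier")


def _impute_nearest(pred: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace flagged epochs with the nearest unflagged prediction
    (earlier epoch wins ties)."""
    good_idx = np.flatnonzero(~bad)
    if len(good_idx) == 0:
        raise ConfigurationError("no scorable epochs to impute from")
    out = pred.copy()
    for i in np.flatnonzero(bad):
        j = good_idx[np.argmin(np.abs(good_idx - i))]
        out[i] = pred[j]
    return out


def _majority3(states: np.ndarray) -> np.ndarray:
    """3-epoch majority filter; a lone epoch flanked by an agreeing pair is
    replaced."""
    out = states.copy()
    same = states[:-2] == states[2:]
    mid_differs = states[1:-1] != states[:-2]
    flip = np.flatnonzero(same & mid_differs) + 1
    out[flip] = states[flip - 1]
    return out


def fit_scorer(features: pd.DataFrame, labels: Mapping[int, str],
               seed: int = 0, **kwargs) -> SleepScorer:
    return SleepScorer(seed=seed, **kwargs).fit(features, labels)


def score_recording(model: SleepScorer, features: pd.DataFrame,
                    epoch_s: float = 10.0, start_zt: float = 0.0) -> Hypnogram:
    return model.predict(features, epoch_s=epoch_s, start_zt=start_zt)


def confusion(truth: Hypnogram, scored: Hypnogram) -> pd.DataFrame:
    """State-by-state confusion matrix (rows = truth, columns = scored)."""
    if truth.n_epochs != scored.n_epochs:
        raise ConfigurationError("hypnogram lengths differ")
    out = pd.DataFrame(0, index=list(STATES), columns=list(STATES))
    for t, s in zip(truth.states, scored.states):
        out.loc[t, s] += 1
    return out


def accuracy(truth: Hypnogram, scored: Hypnogram,
             exclude: np.ndarray | None = None) -> float:
    """Epoch agreement, optionally excluding (e.g. training) epochs."""
    match = truth.states == scored.states
    if exclude is not None:
        keep = np.ones(truth.n_epochs, dtype=bool)
        keep[np.asarray(list(exclude), dtype=int)] = False
        match = match[keep]
    return float(np.mean(match))


def recall(truth: Hypnogram, scored: Hypnogram, state: str,
           exclude: np.ndarray | None = None) -> float:
    """Fraction of the state's true epochs recovered by the scorer."""
    keep = np.ones(truth.n_epochs, dtype=bool)
    if exclude is not None:
        keep[np.asarray(list(exclude), dtype=int)] = False
    sel = (truth.states == state) & keep
    if not sel.any():
        raise ConfigurationError(f"state {state!r} absent from truth")
    return float(np.mean(scored.states[sel] == state))
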
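"""Circular statistics of vigilance-state rhythms.

Time of day is treated as a circular scale: each epoch of a state
contributes a unit vector at angle theta = 2*pi*ZT/24 (epoch midpoint).
The normalized resultant of those vectors summarizes the state's rhythm:
its direction (mean angle) is the peak time of day, and its modulus
(vector length, in [0, 1]) measures phase concentration — 0 for a state
spread uniformly over the day, 1 for one fully consolidated into a single
time point — and is reported as the *relative amplitude* of the rhythm.

Recordings longer than 24 h pool all cycles into one resultant.  No
significance testing is attached; the vector is a descriptive statistic
(the light-entrained design fixes the period at 24 h).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StateAbsentError
from .io import Hypnogram, STATES


@dataclass(frozen=True)
class RhythmVector:
    """Circular mean vector of one state's epoch times."""

    state: str
    mean_angle: float       # radians, in [0, 2*pi)
    peak_zt: float          # hours, = mean_angle * 24 / (2*pi)
    vector_length: float    # dimensionless, in [0, 1]
    n_epochs: int


def state_rhythm_vector(hyp: Hypnogram, state: str) -> RhythmVector:
    """Normalized circular resultant of a state's epoch-midpoint ZTs.

    R = |sum(exp(i*theta))| / n, angle = arg(sum(exp(i*theta))).
    """
    sel = hyp.states == state
    n = int(sel.sum())
    if n == 0:
        raise StateAbsentError(f"state {state!r} absent from hypnogram")
    theta = 2.0 * np.pi * hyp.zt_hours()[sel] / 24.0
    z = np.exp(1j * theta).sum()
    length = float(abs(z)) / n
    angle = float(np.angle(z)) % (2.0 * np.pi)
    if length < 1e-15:
        angle = 0.0  # direction of a (numerically) null resultant is moot
    return RhythmVector(state=state, mean_angle=angle,
                        peak_zt=angle * 24.0 / (2.0 * np.pi),
                        vector_length=min(length, 1.0), n_epochs=n)


def relative_amplitude(hyp: Hypnogram, state: str) -> float:
    """Vector length of the state's rhythm, reported as relative amplitude."""
    return state_rhythm_vector(hyp, state).vector_length


def rhythm_table(hyp: Hypnogram, animal: str = "",
                 states: tuple[str, ...] = STATES) -> pd.DataFrame:
    """Tidy per-animal rhythm vectors: peak ZT, vector length, n epochs."""
    rows = []
    for state in states:
        try:
            v = state_rhythm_vector(hyp, state)
        except StateAbsentError:
            continue
        rows.append({"animal": animal, "state": state,
                     "peak_zt_h": v.peak_zt,
                     "vector_length": v.vector_length,
                     "n_epochs": v.n_epochs})
    return pd.DataFrame(rows, columns=["animal", "state", "peak_zt_h",
                                       "vector_length", "n_epochs"])
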
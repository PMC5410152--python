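"""Character construction from developmental timelines.

Three encodings are provided:

* **continuous** — per species, recorded events are dense-ranked and
  rescaled so the first event sits at 0 and the last at 1; simultaneous
  events share a value.  This makes timing comparable across species
  whose sequences resolve different numbers of stages.
* **decile-binned** — the continuous values cut into ten ordered states
  (0.0-0.09.. -> 0, 0.1-0.19.. -> 1, ..., 1.0 -> 9), suitable for
  cladistic analysis as ordered or unordered characters.
* **event-pair** — one three-state character per unordered event pair
  (i<j): 0 if event i occurs earlier than j, 1 if simultaneous, 2 if
  later.  E events yield E(E-1)/2 characters.

Unknown (``?``) cells propagate as missing; inapplicable (``-``) cells
propagate as inapplicable.  Ranks are computed from recorded events only,
so an unknown event never shifts its neighbours' ranks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .seqdata import (
    INAPP_CODE,
    MISSING_CODE,
    CharacterMatrix,
    TimelineMatrix,
)

__all__ = [
    "ContinuousMatrix",
    "to_continuous",
    "discretize",
    "event_pair_encode",
    "pair_labels",
]


class ContinuousMatrix:
    """Species x event real values in [0, 1] with NaN=unknown, -inf=inapplicable."""

    def __init__(self, species: list[str], event_labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(species), len(event_labels)):
            raise ValueError("values shape mismatch")
        self.species = list(species)
        self.event_labels = list(event_labels)
        self.values = values

    def is_unknown(self) -> np.ndarray:
        return np.isnan(self.values)

    def is_inapplicable(self) -> np.ndarray:
        return np.isneginf(self.values)

    def recorded_mask(self) -> np.ndarray:
        return ~(self.is_unknown() | self.is_inapplicable())


def to_continuous(timelines: TimelineMatrix) -> ContinuousMatrix:
    """Rescale each species' event positions to [0, 1].

    Recorded positions are collapsed to dense ranks 1..P (ties share a
    rank); the value is ``(rank - 1) / (P - 1)``.  A species with fewer
    than two distinct recorded positions has all values set unknown, with
    a warning.
    """
    S, E = timelines.n_species, timelines.n_events
    vals = np.full((S, E), np.nan)
    for i, sp in enumerate(timelines.species):
        row = timelines.positions[i]
        rec = row > 0
        vals[i, row == INAPP_CODE] = -np.inf
        if rec.sum() == 0:
            continue
        pos = row[rec].astype(float)
        n_distinct = len(np.unique(pos))
        if n_distinct < 2:
            warnings.warn(
                f"species {sp!r} has fewer than 2 distinct recorded positions; "
                "continuous values undefined",
                stacklevel=2,
            )
            vals[i, rec] = np.nan
            continue
        ranks = rankdata(pos, method="dense")  # 1..P
        vals[i, rec] = (ranks - 1) / (n_distinct - 1)
    labels = [e.label or f"event_{e.index}" for e in timelines.events]
    return ContinuousMatrix(timelines.species, labels, vals)


def discretize(continuous: ContinuousMatrix) -> CharacterMatrix:
    """Cut continuous values into decile states 0..9 (1.0 clamps to 9).

    State = floor(10 v); the resulting characters are flagged orderable.
    """
    v = continuous.values
    rec = continuous.recorded_mask()
    if ((v[rec] < 0) | (v[rec] > 1)).any():
        raise ValueError("continuous values must lie in [0, 1]")
    states = np.full(v.shape, MISSING_CODE, dtype=np.int8)
    states[continuous.is_inapplicable()] = INAPP_CODE
    states[rec] = np.minimum(np.floor(10 * v[rec]), 9).astype(np.int8)
    return CharacterMatrix(
        continuous.species, list(continuous.event_labels), states, ordered=True
    )


def pair_labels(n_events: int) -> list[tuple[int, int]]:
    """Ascending (i, j) event-index pairs, i < j, 1-based."""
    return [(i, j) for i in range(1, n_events + 1) for j in range(i + 1, n_events + 1)]


def event_pair_encode(timelines: TimelineMatrix) -> CharacterMatrix:
    """Encode each unordered event pair as a three-state character.

    For pair (i, j) with i < j: state 0 if event i occurs at an earlier
    position than j, 1 if simultaneous, 2 if later.  ``?`` if either
    event is unknown in that species, ``-`` if either is inapplicable.
    """
    E = timelines.n_events
    if E < 2:
        raise ValueError("event-pair coding needs at least 2 events")
    pairs = pair_labels(E)
    S = timelines.n_species
    states = np.empty((S, len(pairs)), dtype=np.int8)
    pos = timelines.positions
    for c, (i, j) in enumerate(pairs):
        a, b = pos[:, i - 1], pos[:, j - 1]
        col = np.where(a < b, 0, np.where(a == b, 1, 2)).astype(np.int8)
        col[(a == MISSING_CODE) | (b == MISSING_CODE)] = MISSING_CODE
        col[(a == INAPP_CODE) | (b == INAPP_CODE)] = INAPP_CODE
        states[:, c] = col
    ids = [f"{i}v{j}" for i, j in pairs]
    return CharacterMatrix(timelines.species, ids, states, ordered=False)
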
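"""Assign pooled events back to barcode keys.

Two procedures are provided:

*Separation-threshold assignment* (the automated route). Each event's
barcode channels are arcsinh-transformed and rescaled to [0, 1]; for every
key the score is the lowest key-positive rescaled value minus the highest
key-negative one. The best-scoring key wins and the winning score, clamped
to [0, 1], is the event's *separation* — the gap between the dimmest
barcode channel that should be on and the brightest that should be off.
Doublets carry the union of two keys, so some channel violates every key's
negative slot and their separation collapses toward 0. Events below the
separation threshold (0.3 by default) are left unassigned.

*Hierarchical Boolean gating* (the manual route, automated here). A fixed
per-channel cutoff splits each barcode channel into +/-; an event is
assigned to the unique key whose positive set exactly matches its
above-cutoff set. Cutoffs can be supplied or estimated per channel by
minimising within-class variance (Otsu's criterion on the 1-D values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcs_io import EventMatrix
from .preprocess import (
    DEFAULT_COFACTOR,
    arcsinh_transform,
    rescale_barcode_channels,
)
from .scheme import BarcodeScheme

#: assigned_sample value for events not attributable to any key
UNASSIGNED = -1


class DebarcodeError(ValueError):
    pass


@dataclass
class DebarcodeParams:
    """Separation-threshold debarcoding parameters.

    ``separation_threshold`` defaults to 0.3: events whose separation is
    below it are discarded as unassignable (ambiguous staining or doublets).
    """

    separation_threshold: float = 0.3
    cofactor: float = DEFAULT_COFACTOR
    lo_pct: float = 1.0
    hi_pct: float = 99.0

    def validate(self) -> None:
        if not 0 <= self.separation_threshold <= 1:
            raise DebarcodeError(
                f"separation_threshold must be in [0, 1], got {self.separation_threshold}"
            )
        if self.cofactor <= 0:
            raise DebarcodeError("cofactor must be > 0")


@dataclass
class DebarcodeAssignment:
    """Per-event call: sample index (or UNASSIGNED), separation score in
    [0, 1], and the rescaled barcode matrix the scores came from."""

    assigned_sample: np.ndarray
    separation: np.ndarray
    rescaled: np.ndarray

    def __post_init__(self) -> None:
        self.assigned_sample = np.asarray(self.assigned_sample, dtype=np.int64)
        self.separation = np.asarray(self.separation, dtype=float)
        if not (
            self.assigned_sample.size == self.separation.size == self.rescaled.shape[0]
        ):
            raise DebarcodeError("assignment field lengths differ")

    def __len__(self) -> int:
        return self.assigned_sample.size

    @property
    def is_assigned(self) -> np.ndarray:
        return self.assigned_sample != UNASSIGNED


@dataclass
class ChannelThresholds:
    """Per-barcode-channel positive cutoff (arcsinh-transformed units).

    ``failed[j]`` marks channels where no cutoff could be estimated
    (degenerate/constant data); their threshold is +inf, so nothing is
    called positive there.
    """

    values: np.ndarray
    failed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.failed is None:
            self.failed = np.zeros(self.values.size, dtype=bool)
        self.failed = np.asarray(self.failed, dtype=bool)
        if np.isnan(self.values).any():
            raise DebarcodeError("channel thresholds must not be NaN")


def _key_scores(rescaled: np.ndarray, scheme: BarcodeScheme) -> np.ndarray:
    """Events x samples score matrix: min over key-positive channels minus
    max over key-negative channels of the rescaled intensities."""
    n, b = rescaled.shape
    if b != scheme.n_channels:
        raise DebarcodeError(
            f"rescaled matrix has {b} columns but scheme has "
            f"{scheme.n_channels} channels"
        )
    scores = np.empty((n, scheme.n_samples))
    for s in range(scheme.n_samples):
        pos = scheme.key_matrix[s].astype(bool)
        # empty positive set scores 1 (vacuous min), empty negative set 0
        min_pos = rescaled[:, pos].min(axis=1) if pos.any() else np.ones(n)
        max_neg = rescaled[:, ~pos].max(axis=1) if (~pos).any() else np.zeros(n)
        scores[:, s] = min_pos - max_neg
    return scores


def assign_events(
    rescaled: np.ndarray, scheme: BarcodeScheme
) -> DebarcodeAssignment:
    """Preliminary assignment: best-scoring key per event, no threshold.

    Exact score ties between distinct keys are unassignable and get
    separation 0. Separation is the winning score clamped to [0, 1].
    """
    rescaled = np.asarray(rescaled, dtype=float)
    scores = _key_scores(rescaled, scheme)
    best = scores.argmax(axis=1)
    best_score = scores[np.arange(len(best)), best]
    tied = (scores == best_score[:, None]).sum(axis=1) > 1
    assigned = best.astype(np.int64)
    assigned[tied] = UNASSIGNED
    separation = np.clip(best_score, 0.0, 1.0)
    separation[tied] = 0.0
    return DebarcodeAssignment(assigned, separation, rescaled)


def apply_threshold(
    assignment: DebarcodeAssignment, params: DebarcodeParams
) -> DebarcodeAssignment:
    """Final assignment: unassign events with separation below threshold.

    The comparison is ``>=``: an event exactly at the threshold is kept.
    """
    params.validate()
    assigned = assignment.assigned_sample.copy()
    assigned[assignment.separation < params.separation_threshold] = UNASSIGNED
    return DebarcodeAssignment(
        assigned, assignment.separation.copy(), assignment.rescaled
    )


def debarcode_separation(
    matrix: EventMatrix,
    scheme: BarcodeScheme,
    params: DebarcodeParams | None = None,
) -> DebarcodeAssignment:
    """End-to-end separation-threshold debarcoding of an event matrix.

    Extracts the scheme's barcode channels, arcsinh-transforms, rescales
    per channel, scores every key, and applies the separation threshold.
    """
    params = params or DebarcodeParams()
    params.validate()
    cols = [matrix.channel_index(cid) for cid in scheme.channel_ids]
    transformed = arcsinh_transform(matrix.values[:, cols], params.cofactor)
    rescaled = rescale_barcode_channels(transformed, params.lo_pct, params.hi_pct)
    return apply_threshold(assign_events(rescaled, scheme), params)


def hierarchical_gate_debarcode(
    transformed: np.ndarray,
    scheme: BarcodeScheme,
    thresholds: ChannelThresholds,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> DebarcodeAssignment:
    """Boolean-gate assignment with fixed per-channel cutoffs.

    An event goes to sample ``s`` iff it is strictly above the cutoff on
    every key-positive channel of ``s`` and at or below the cutoff on every
    key-negative channel; in a constant-weight scheme at most one key can
    match. The separation field is populated from percentile-rescaled
    values so gated results remain comparable in QC reports.
    """
    transformed = np.atleast_2d(np.asarray(transformed, dtype=float))
    if thresholds.values.size != scheme.n_channels:
        raise DebarcodeError(
            f"{thresholds.values.size} thresholds for "
            f"{scheme.n_channels} barcode channels"
        )
    above = transformed > thresholds.values[None, :]
    key_bool = scheme.key_matrix.astype(bool)
    assigned = np.full(transformed.shape[0], UNASSIGNED, dtype=np.int64)
    for s in range(scheme.n_samples):
        assigned[(above == key_bool[s][None, :]).all(axis=1)] = s

    if transformed.shape[0] >= 2:
        rescaled = rescale_barcode_channels(transformed, lo_pct, hi_pct)
    else:
        rescaled = np.clip(transformed, 0.0, 1.0)
    scores = _key_scores(rescaled, scheme)
    separation = np.clip(scores.max(axis=1), 0.0, 1.0)
    hit = assigned != UNASSIGNED
    separation[hit] = np.clip(scores[np.flatnonzero(hit), assigned[hit]], 0.0, 1.0)
    return DebarcodeAssignment(assigned, separation, rescaled)


def _otsu_split(values: np.ndarray) -> float | None:
    """Cutoff minimising total within-class sum of squares; None if the
    channel is degenerate (constant)."""
    v = np.sort(values.astype(float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        return None
    s1 = np.cumsum(v)
    s2 = np.cumsum(v * v)
    # left class = first i values, i in 1..n-1
    i = np.arange(1, n)
    ss_left = s2[i - 1] - s1[i - 1] ** 2 / i
    ss_right = (s2[-1] - s2[i - 1]) - (s1[-1] - s1[i - 1]) ** 2 / (n - i)
    within = ss_left + ss_right
    # a split between equal values is not realisable by a threshold
    within[v[i] == v[i - 1]] = np.inf
    best = int(np.argmin(within))
    return float((v[best] + v[best + 1]) / 2.0)


def estimate_channel_thresholds(transformed: np.ndarray) -> ChannelThresholds:
    """Per-channel positive cutoff by within-class variance minimisation.

    Deterministic (first minimal split wins). A constant channel is flagged
    failed and given a +inf cutoff.
    """
    x = np.atleast_2d(np.asarray(transformed, dtype=float))
    if x.shape[0] < 2:
        raise DebarcodeError(f"threshold estimation needs >= 2 events, got {x.shape[0]}")
    values = np.empty(x.shape[1])
    failed = np.zeros(x.shape[1], dtype=bool)
    for j in range(x.shape[1]):
        cut = _otsu_split(x[:, j])
        if cut is None:
            values[j] = np.inf
            failed[j] = True
        else:
            values[j] = cut
    return ChannelThresholds(values, failed)


def debarcode_hierarchical(
    matrix: EventMatrix,
    scheme: BarcodeScheme,
    thresholds: ChannelThresholds | None = None,
    cofactor: float = DEFAULT_COFACTOR,
) -> DebarcodeAssignment:
    """End-to-end hierarchical-gating debarcoding of an event matrix.

    Cutoffs are estimated per channel when not supplied.
    """
    cols = [matrix.channel_index(cid) for cid in scheme.channel_ids]
    transformed = arcsinh_transform(matrix.values[:, cols], cofactor)
    if thresholds is None:
        thresholds = estimate_channel_thresholds(transformed)
    return hierarchical_gate_debarcode(transformed, scheme, thresholds)
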
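"""Event cleanup and intensity transformation before debarcoding.

Cell events are identified by DNA (rhodium) intensity together with the
event-length pulse parameter; dead cells are removed on palladium uptake.
Gates operate on arcsinh-transformed intensities (the standard CyTOF
variance-stabilising transform) so thresholds are scale-stable, except the
event-length gate which uses the raw pulse length.

Barcode channels are rescaled per channel to [0, 1] between robust
percentiles before separation scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fcs_io import EventMatrix

DEFAULT_COFACTOR = 5.0


class PreprocessError(ValueError):
    pass


@dataclass
class GateConfig:
    """Cell-identification and viability gate settings.

    ``rh_min`` and ``pd_max`` are in arcsinh-transformed units;
    ``length_range`` is in raw event-length units.
    """

    rh_channel: str = "Rh103Di"
    rh_min: float = 0.0
    length_channel: str = "Event_length"
    length_range: tuple[float, float] = (-np.inf, np.inf)
    pd_channel: str = "Pd106Di"
    pd_max: float = np.inf
    cofactor: float = DEFAULT_COFACTOR

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise PreprocessError(f"length_range lo > hi: {self.length_range}")
        if np.isnan(self.rh_min) or np.isnan(self.pd_max):
            raise PreprocessError("gate thresholds must not be NaN")
        if self.cofactor <= 0:
            raise PreprocessError("cofactor must be > 0")


def arcsinh_transform(values, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Elementwise asinh(x / cofactor); strictly monotone."""
    if cofactor <= 0:
        raise PreprocessError(f"cofactor must be > 0, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def gate_cells(
    matrix: EventMatrix, gate: GateConfig
) -> tuple[EventMatrix, np.ndarray]:
    """Keep events with transformed Rh >= rh_min and event length in range.

    Returns the retained subset and the kept row indices (for traceability
    back to the original batch).
    """
    gate.validate()
    rh = arcsinh_transform(matrix.column(gate.rh_channel), gate.cofactor)
    length = matrix.column(gate.length_channel)
    lo, hi = gate.length_range
    keep = (rh >= gate.rh_min) & (length >= lo) & (length <= hi)
    kept = np.flatnonzero(keep)
    return matrix.take(kept), kept


def gate_live(
    matrix: EventMatrix, gate: GateConfig
) -> tuple[EventMatrix, np.ndarray]:
    """Keep events with transformed Pd <= pd_max (remove dead cells)."""
    gate.validate()
    pd = arcsinh_transform(matrix.column(gate.pd_channel), gate.cofactor)
    kept = np.flatnonzero(pd <= gate.pd_max)
    return matrix.take(kept), kept


def rescale_barcode_channels(
    transformed: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> np.ndarray:
    """Rescale each column to [0, 1] between its lo/hi percentiles.

    Per column: subtract the ``lo_pct`` percentile, divide by the
    percentile range, clamp to [0, 1]. A constant column cannot be rescaled
    and becomes all zeros (with a warning) — nothing looks positive there.
    """
    if not 0 <= lo_pct < hi_pct <= 100:
        raise PreprocessError(f"need 0 <= lo_pct < hi_pct <= 100, got {lo_pct}, {hi_pct}")
    x = np.atleast_2d(np.asarray(transformed, dtype=float))
    if x.shape[0] < 2:
        raise PreprocessError(f"rescaling needs >= 2 events, got {x.shape[0]}")
    lo = np.percentile(x, lo_pct, axis=0)
    hi = np.percentile(x, hi_pct, axis=0)
    span = hi - lo
    out = np.zeros_like(x)
    for j in range(x.shape[1]):
        if span[j] <= 0:
            warnings.warn(
                f"barcode column {j} is constant over its percentile range; "
                "rescaled to all zeros",
                stacklevel=2,
            )
            continue
        out[:, j] = np.clip((x[:, j] - lo[j]) / span[j], 0.0, 1.0)
    return out
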
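"""Yield/QC statistics for a debarcoded batch and ground-truth concordance.

The headline statistic is the *capture rate*: the fraction of live, gated
cells that the debarcoder assigned to a barcode. The per-sample breakdown
(each barcode's share of assigned events) is the per-batch distribution
view — for an equal-abundance pool every barcode should hold roughly
1/S of the assigned events. Against simulator ground truth the concordance
report scores singlet accuracy and doublet rejection with a full
truth x call confusion table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .debarcode import UNASSIGNED, DebarcodeAssignment
from .simulate import GroundTruth

REPORT_SCHEMA_VERSION = "1"

#: separation-histogram bin width (diagnostic convention)
SEPARATION_BIN_WIDTH = 0.02


class ReportError(ValueError):
    pass


@dataclass
class SampleYield:
    """One barcode's slice of the batch."""

    sample: str
    count: int
    fraction_of_assigned: float
    fraction_of_live: float


@dataclass
class YieldReport:
    total_events: int
    gated_cells: int
    live_cells: int
    assigned: int
    capture_rate: float
    per_sample: list[SampleYield]
    separation_histogram: list[int]
    empty: bool = False  # true when there were no live cells to assign


@dataclass
class ConcordanceReport:
    """Agreement with simulator ground truth.

    ``singlet_accuracy`` is the fraction of *assigned* singlets whose call
    matches their true sample; ``doublet_rejection`` the fraction of true
    doublets left unassigned. Either is NaN when its denominator is empty.
    ``confusion_counts`` is S x (S+1): one row per true sample, columns are
    the S called samples plus a final unassigned column.
    """

    singlet_accuracy: float
    doublet_rejection: float
    confusion_counts: np.ndarray
    n_singlets: int
    n_doublets: int


def compute_yield(
    assignment: DebarcodeAssignment,
    sample_names: list[str],
    total_events: int | None = None,
    gated_cells: int | None = None,
    live_cells: int | None = None,
) -> YieldReport:
    """Summarise a final assignment into a :class:`YieldReport`.

    The counts from preprocessing give the funnel: ``total_events`` in the
    raw batch, ``gated_cells`` after the cell gate, ``live_cells`` after
    the viability gate (defaults to the assignment length — the events that
    actually reached the debarcoder). Capture rate = assigned / live_cells.
    """
    n = len(assignment)
    live = n if live_cells is None else live_cells
    gated = live if gated_cells is None else gated_cells
    total = gated if total_events is None else total_events

    s_count = len(sample_names)
    counts = np.bincount(
        assignment.assigned_sample[assignment.is_assigned], minlength=s_count
    )
    if counts.size > s_count:
        raise ReportError(
            f"assignment references sample index >= {s_count}"
        )
    assigned = int(counts.sum())

    if live == 0:
        return YieldReport(
            total_events=total, gated_cells=gated, live_cells=0, assigned=0,
            capture_rate=0.0,
            per_sample=[SampleYield(nm, 0, 0.0, 0.0) for nm in sample_names],
            separation_histogram=[0] * int(round(1 / SEPARATION_BIN_WIDTH)),
            empty=True,
        )

    per_sample = [
        SampleYield(
            sample=nm,
            count=int(c),
            fraction_of_assigned=float(c / assigned) if assigned else 0.0,
            fraction_of_live=float(c / live),
        )
        for nm, c in zip(sample_names, counts)
    ]
    n_bins = int(round(1 / SEPARATION_BIN_WIDTH))
    hist, _ = np.histogram(assignment.separation, bins=n_bins, range=(0.0, 1.0))
    return YieldReport(
        total_events=total,
        gated_cells=gated,
        live_cells=live,
        assigned=assigned,
        capture_rate=assigned / live,
        per_sample=per_sample,
        separation_histogram=[int(c) for c in hist],
    )


def score_concordance(
    assignment: DebarcodeAssignment, truth: GroundTruth
) -> ConcordanceReport:
    """Score an assignment against simulator ground truth."""
    if len(assignment) != len(truth):
        raise ReportError(
            f"assignment has {len(assignment)} events, truth has {len(truth)}"
        )
    calls = assignment.assigned_sample
    singlet = ~truth.is_doublet
    doublet = truth.is_doublet

    s_count = int(truth.true_sample[singlet].max()) + 1 if singlet.any() else 0
    if singlet.any():
        s_count = max(s_count, int(calls[calls != UNASSIGNED].max(initial=-1)) + 1)
    confusion = np.zeros((s_count, s_count + 1), dtype=np.int64)
    for t, c in zip(truth.true_sample[singlet], calls[singlet]):
        confusion[t, s_count if c == UNASSIGNED else c] += 1

    assigned_singlet = singlet & (calls != UNASSIGNED)
    n_assigned_singlets = int(assigned_singlet.sum())
    singlet_accuracy = (
        float(
            (calls[assigned_singlet] == truth.true_sample[assigned_singlet]).mean()
        )
        if n_assigned_singlets
        else math.nan
    )
    n_doublets = int(doublet.sum())
    doublet_rejection = (
        float((calls[doublet] == UNASSIGNED).mean()) if n_doublets else math.nan
    )
    return ConcordanceReport(
        singlet_accuracy=singlet_accuracy,
        doublet_rejection=doublet_rejection,
        confusion_counts=confusion,
        n_singlets=int(singlet.sum()),
        n_doublets=n_doublets,
    )


def _nan_to_none(x: float):
    return None if isinstance(x, float) and math.isnan(x) else x


def report_to_dict(
    yield_report: YieldReport, concordance: ConcordanceReport | None = None
) -> dict:
    """Machine-readable report (JSON-serialisable, versioned schema)."""
    out: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "total_events": yield_report.total_events,
        "gated_cells": yield_report.gated_cells,
        "live_cells": yield_report.live_cells,
        "assigned": yield_report.assigned,
        "capture_rate": yield_report.capture_rate,
        "empty": yield_report.empty,
        "per_sample": [
            {
                "sample": s.sample,
                "count": s.count,
                "fraction_of_assigned": s.fraction_of_assigned,
                "fraction_of_live": s.fraction_of_live,
            }
            for s in yield_report.per_sample
        ],
        "separation_histogram": {
            "bin_width": SEPARATION_BIN_WIDTH,
            "counts": yield_report.separation_histogram,
        },
    }
    if concordance is not None:
        out["concordance"] = {
            "singlet_accuracy": _nan_to_none(concordance.singlet_accuracy),
            "doublet_rejection": _nan_to_none(concordance.doublet_rejection),
            "n_singlets": concordance.n_singlets,
            "n_doublets": concordance.n_doublets,
            "confusion_counts": concordance.confusion_counts.tolist(),
        }
    return out


def render_report(
    yield_report: YieldReport, concordance: ConcordanceReport | None = None
) -> tuple[dict, str]:
    """Return (JSON-ready dict, human-readable text table).

    The capture rate is printed as a percentage with two decimals.
    """
    d = report_to_dict(yield_report, concordance)
    lines = [
        "Debarcoding yield report",
        "========================",
        f"total events     : {yield_report.total_events}",
        f"gated cells      : {yield_report.gated_cells}",
        f"live cells       : {yield_report.live_cells}",
        f"assigned         : {yield_report.assigned}",
        f"capture rate     : {yield_report.capture_rate * 100:.2f}%",
        "",
        f"{'sample':<12}{'count':>10}{'% of assigned':>16}{'% of live':>12}",
    ]
    for s in yield_report.per_sample:
        lines.append(
            f"{s.sample:<12}{s.count:>10}"
            f"{s.fraction_of_assigned * 100:>15.2f}%"
            f"{s.fraction_of_live * 100:>11.2f}%"
        )
    unassigned = yield_report.live_cells - yield_report.assigned
    un_frac = unassigned / yield_report.live_cells if yield_report.live_cells else 0.0
    lines.append(
        f"{'unassigned':<12}{unassigned:>10}{'':>16}{un_frac * 100:>11.2f}%"
    )
    if concordance is not None:
        lines += ["", "Concordance with ground truth", "-----------------------------"]
        acc = concordance.singlet_accuracy
        rej = concordance.doublet_rejection
        lines.append(
            "singlet accuracy : "
            + (f"{acc * 100:.2f}%" if not math.isnan(acc) else "n/a")
        )
        lines.append(
            "doublet rejection: "
            + (f"{rej * 100:.2f}%" if not math.isnan(rej) else "n/a")
        )
    return d, "\n".join(lines)


def write_report_json(
    path, yield_report: YieldReport, concordance: ConcordanceReport | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(yield_report, concordance), fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_per_sample_fractions(yield_report: YieldReport, path) -> None:
    """Bar chart of each barcode's share of assigned events (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.sample for s in yield_report.per_sample]
    fracs = [s.fraction_of_assigned * 100 for s in yield_report.per_sample]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(names)), 3.5))
    ax.bar(names, fracs, color="#4878b0")
    if names:
        ax.axhline(100 / len(names), ls="--", c="grey", lw=1)
    ax.set_ylabel("% of assigned events")
    ax.set_xlabel("barcode")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
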
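"""Neurite tortuosity and neurite-to-plaque distance from traced polylines.

Curvature ratio is the path length of a traced axon segment divided by its
end-to-end (chord) distance: 1 for a perfectly straight segment, larger the
more the neurite meanders.  Only segments longer than 20 μm are measured
(shorter ones cannot be followed reliably).  Distance to a plaque is the
mean of the distances from the two endpoints and the arc-length midpoint of
the segment to the nearest plaque-border pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NeuriteTrace",
    "TraceTooShort",
    "curvature_ratio",
    "neurite_plaque_distance",
    "load_traces",
    "trace_table",
]

MIN_TRACE_LENGTH_UM = 20.0


class TraceTooShort(ValueError):
    """Trace below the 20 μm traceability floor; excluded from analysis."""


@dataclass
class NeuriteTrace:
    """An ordered polyline of (y, x) μm coordinates for one traced segment."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 2 or (np.ptp(self.points, axis=0) == 0).all():
            raise ValueError("a trace needs at least 2 distinct points")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.sqrt((np.diff(self.points, axis=0) ** 2).sum(axis=1))

    @property
    def length_um(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def end_to_end_um(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    def arc_midpoint(self) -> np.ndarray:
        """Point at half the total arc length, interpolated along the polyline."""
        target = self.length_um / 2.0
        cum = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        i = int(np.searchsorted(cum, target, side="right")) - 1
        i = min(i, len(self.points) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (target - cum[i]) / seg
        return self.points[i] + t * (self.points[i + 1] - self.points[i])


def curvature_ratio(trace: NeuriteTrace) -> float:
    """Path length over end-to-end distance (≥ 1; exactly 1 when straight)."""
    if trace.length_um <= MIN_TRACE_LENGTH_UM:
        raise TraceTooShort(
            f"trace length {trace.length_um:.2f} μm is below the {MIN_TRACE_LENGTH_UM} μm floor"
        )
    chord = trace.end_to_end_um
    if chord == 0:
        raise ValueError("closed loop: end-to-end distance is zero")
    return trace.length_um / chord


def neurite_plaque_distance(
    trace: NeuriteTrace,
    plaque_border: np.ndarray,
    pixel_size_um: float = 1.0,
) -> float:
    """Mean distance (μm) from the trace's two ends and arc-length midpoint to the border.

    ``plaque_border`` is either a 2D boolean border mask (pixel grid scaled by
    ``pixel_size_um``) or an (n, 2) array of border (y, x) μm coordinates.
    Returns NaN for an empty border.
    """
    border = np.asarray(plaque_border)
    if border.ndim == 2 and border.dtype == bool:
        pts = np.argwhere(border) * pixel_size_um
    else:
        pts = border.reshape(-1, 2).astype(float)
    if len(pts) == 0:
        return float("nan")
    samples = np.stack([trace.points[0], trace.arc_midpoint(), trace.points[-1]])
    d = np.min(
        np.hypot(
            samples[:, 0][:, None] - pts[:, 0][None, :],
            samples[:, 1][:, None] - pts[:, 1][None, :],
        ),
        axis=1,
    )
    return float(d.mean())


def load_traces(path: str | Path) -> list[NeuriteTrace]:
    """Read polylines from JSON ([{"points": [[y, x], ...]}, ...]) or CSV
    (columns trace_id, y_um, x_um; points in row order)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [NeuriteTrace(np.asarray(r["points"], dtype=float)) for r in records]
    df = pd.read_csv(path)
    return [
        NeuriteTrace(g[["y_um", "x_um"]].to_numpy(float))
        for _, g in df.groupby("trace_id", sort=True)
    ]


def trace_table(
    traces: list[NeuriteTrace],
    plaque_border: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Per-trace metrics; too-short traces are kept with a reason code, not a value."""
    rows = []
    for i, tr in enumerate(traces):
        row: dict = {
            "trace_id": i,
            "length_um": tr.length_um,
            "end_to_end_um": tr.end_to_end_um,
        }
        try:
            row["curvature_ratio"] = curvature_ratio(tr)
            row["excluded_reason"] = ""
        except TraceTooShort:
            row["curvature_ratio"] = np.nan
            row["excluded_reason"] = "below_20um_floor"
        if plaque_border is not None:
            row["plaque_distance_um"] = neurite_plaque_distance(tr, plaque_border, pixel_size_um)
        rows.append(row)
    return pd.DataFrame(rows)
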
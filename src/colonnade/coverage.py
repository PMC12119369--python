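"""Trimmed cell size, coverage factor and completeness per cell type.

Columnar neurons have a clear home column but sprinkle a few synapses into
neighbouring columns, so the raw count of innervated columns overestimates
cell size.  The trimming procedure ranks each neuron's columns by synapse
count, takes the median cumulative-fraction-vs-rank curve across neurons of
the type, finds the rank of highest curvature (rank*) with the kneedle
knee detector (concave increasing, sensitivity S = 1, with the point (0,0)
prepended), and discards, per neuron, all synapses in columns with fewer
synapses than that neuron's rank-rank* column (ties retained together).
If the median cumulative fraction at rank* is below 0.775 the knee is
considered unreliable and rank* falls back to the first rank reaching
0.995 (or, failing that, the last rank attaining the curve maximum).

From the trimmed assignments: cell size = median trimmed columns per cell;
coverage factor = mean number of cells contributing to an occupied column.
Columnar completeness (occupied / total columns) and the convex-hull column
area use the raw, untrimmed occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import InsufficientDataError
from .hexgrid import axial_to_xy

__all__ = [
    "FALLBACK_MIN_FRACTION",
    "FALLBACK_TARGET_FRACTION",
    "cumulative_fraction_curve",
    "kneedle_knee",
    "knee_rank",
    "trim_neuron",
    "CoverageSummary",
    "coverage_summary",
    "column_counts",
]

FALLBACK_MIN_FRACTION = 0.775
FALLBACK_TARGET_FRACTION = 0.995

#: area of one hexagonal column at unit centre spacing (hexagon with
#: inradius spacing/2): sqrt(3)/2
_COLUMN_AREA_UNIT = np.sqrt(3.0) / 2.0


def cumulative_fraction_curve(
    per_neuron_counts: dict,
) -> tuple[dict, np.ndarray]:
    """Per-neuron cumulative synapse fraction vs column rank, plus the median.

    ``per_neuron_counts`` maps neuron id to a Series/dict of synapse counts
    per column.  Columns are ranked by descending count; curves of different
    lengths are padded with 1.0 before taking the element-wise median.
    Neurons with zero synapses are excluded with a warning.
    """
    curves = {}
    for nid, counts in per_neuron_counts.items():
        c = np.sort(np.asarray(pd.Series(counts), dtype=float))[::-1]
        total = c.sum()
        if total <= 0:
            warnings.warn(f"neuron {nid} has zero synapses; excluded", stacklevel=2)
            continue
        curves[nid] = np.cumsum(c) / total
    if not curves:
        raise InsufficientDataError("no neurons with synapses")
    m = max(len(c) for c in curves.values())
    padded = np.stack([np.pad(c, (0, m - len(c)), constant_values=1.0) for c in curves.values()])
    return curves, np.median(padded, axis=0)


def kneedle_knee(x: np.ndarray, y: np.ndarray, S: float = 1.0) -> int | None:
    """Knee of a concave increasing curve by the kneedle algorithm.

    Both axes are normalized to [0, 1]; the knee is the first local maximum
    of the difference curve y_n - x_n whose height the difference later
    drops below by more than S times the mean x-step before the next local
    maximum.  Returns the x value (int rank) of the knee, or None when the
    difference curve has no qualifying local maximum (e.g. a straight
    line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return None
    xn = (x - x[0]) / (x[-1] - x[0])
    yspan = y.max() - y.min()
    if yspan == 0:
        return None
    yn = (y - y.min()) / yspan
    diff = yn - xn
    n = len(diff)
    lmx = [i for i in range(1, n - 1) if diff[i] > diff[i - 1] and diff[i] >= diff[i + 1]]
    if not lmx:
        return None
    step = S * float(np.mean(np.diff(xn)))
    for k, i in enumerate(lmx):
        thresh = diff[i] - step
        stop = lmx[k + 1] if k + 1 < len(lmx) else n
        for j in range(i + 1, stop):
            if diff[j] < thresh:
                return int(round(x[i]))
    return None


def knee_rank(median_curve: np.ndarray) -> int:
    """rank* for trimming, from the median cumulative-fraction curve.

    The curve is indexed by rank starting at 1; the point (0, 0) is
    prepended before knee detection.  Applies the unreliable-knee fallback
    rules described in the module docstring.
    """
    y = np.asarray(median_curve, dtype=float)
    if len(y) == 0:
        raise InsufficientDataError("empty curve")
    x = np.arange(0, len(y) + 1)
    yy = np.concatenate([[0.0], y])
    knee = kneedle_knee(x, yy, S=1.0)
    if knee is not None and knee >= 1 and y[knee - 1] >= FALLBACK_MIN_FRACTION:
        return int(knee)
    reached = np.nonzero(y >= FALLBACK_TARGET_FRACTION)[0]
    if len(reached):
        return int(reached[0]) + 1
    # 0.995 never reached: last rank attaining the curve maximum (flagged)
    warnings.warn("cumulative curve never reaches the fallback target; using its maximum",
                  stacklevel=2)
    return int(np.nonzero(y == y.max())[0][-1]) + 1


def trim_neuron(counts, rank_star: int):
    """Columns of one neuron retained after trimming at rank*.

    ``counts`` maps column to synapse count.  The neuron keeps every column
    whose count is at least the count of its own rank-rank* column, so tied
    columns are retained together; a rank* beyond the neuron's occupied
    columns keeps everything.
    """
    s = pd.Series(counts, dtype=float)
    if rank_star >= len(s):
        return list(s.index)
    cutoff = np.sort(s.to_numpy())[::-1][rank_star - 1]
    return list(s.index[s >= cutoff])


@dataclass
class CoverageSummary:
    """Spatial coverage metrics of one cell type in one neuropil."""

    type_name: str
    neuropil: str
    rank_star: int
    cell_size: float  # median trimmed columns per cell
    coverage_factor: float  # mean cells per occupied column (trimmed)
    columnar_completeness: float  # occupied / total columns (untrimmed)
    column_area: float  # convex-hull area in column units (or occupied count)
    n_cells: int
    occupied_columns: int


def column_counts(synapses: pd.DataFrame) -> dict:
    """Per-neuron synapse counts per (p, q) column from an assigned table."""
    out = {}
    for nid, grp in synapses.groupby("neuron_id", sort=True):
        out[nid] = grp.groupby(["p", "q"]).size()
    return out


def coverage_summary(
    per_neuron_counts: dict,
    total_columns: int,
    type_name: str = "",
    neuropil: str = "",
    use_hull: bool = True,
) -> CoverageSummary:
    """All four coverage metrics for one type.

    ``use_hull=False`` substitutes the occupied-column count for the hull
    area (for types whose hull badly misrepresents the covered area, e.g.
    ring- or arc-shaped coverage).
    """
    _, median_curve = cumulative_fraction_curve(per_neuron_counts)
    rank_star = knee_rank(median_curve)
    trimmed = {nid: trim_neuron(c, rank_star) for nid, c in per_neuron_counts.items()
               if pd.Series(c).sum() > 0}

    sizes = np.array([len(cols) for cols in trimmed.values()], dtype=float)
    cells_per_column: dict = {}
    for cols in trimmed.values():
        for col in cols:
            cells_per_column[col] = cells_per_column.get(col, 0) + 1
    occupied_trimmed = len(cells_per_column)
    coverage_factor = (
        float(np.mean(list(cells_per_column.values()))) if occupied_trimmed else 0.0
    )

    raw_columns = set()
    for c in per_neuron_counts.values():
        raw_columns.update(pd.Series(c).index)
    completeness = len(raw_columns) / total_columns if total_columns else 0.0

    if use_hull and len(raw_columns) >= 1:
        pq = np.array([(p, q) for p, q in raw_columns], dtype=float)
        xy = axial_to_xy(pq[:, 0], pq[:, 1], 1.0)
        # hull around the hexagonal column footprints (centre + 6 corners at
        # the hexagon circumradius 1/sqrt(3)), so a dense convex patch never
        # under-counts its own columns
        ang = np.pi / 6 + np.arange(6) * np.pi / 3
        corners = np.stack([np.cos(ang), np.sin(ang)], axis=1) / np.sqrt(3.0)
        pts = (xy[:, None, :] + corners[None, :, :]).reshape(-1, 2)
        try:
            area = float(ConvexHull(pts).volume) / _COLUMN_AREA_UNIT
        except QhullError:  # degenerate occupancy
            area = float(len(raw_columns))
    else:
        area = float(len(raw_columns))

    return CoverageSummary(
        type_name=type_name,
        neuropil=neuropil,
        rank_star=rank_star,
        cell_size=float(np.median(sizes)),
        coverage_factor=coverage_factor,
        columnar_completeness=completeness,
        column_area=area,
        n_cells=len(trimmed),
        occupied_columns=len(raw_columns),
    )
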
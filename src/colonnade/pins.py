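"""Curved column centre lines ("pins") built from synapse clouds.

A pin models one column's centre line as an ordered polyline of ``n_samp``
3D points running from the top of a neuropil to its bottom.  Construction
follows an eight-step pipeline: (1) collect the synapse positions assigned
to the column; (2) PCA, orienting PC1 top-to-bottom; (3) drop lateral
outliers beyond ``f_lat`` times the RMS lateral distance; (4) normalize the
PC1 projection to t in [-1, 1]; (5) estimate the top/bottom endpoints by
intersecting subset-PCA axes with the bounding surfaces; (6) rank-order the
points by t and smooth with a sliding window of ``n_avg`` neighbours;
(7) extract the shortest order-preserving sublist whose consecutive gaps do
not exceed ``d_max`` = |r_top - r_bottom| / ``n_tang``; (8) resample to
``n_samp`` points uniformly in arc length with shape-preserving (PCHIP)
interpolation.

The medulla uses two separate endpoint PCAs on the top/bottom point
fractions; thinner neuropils use a single PCA over all points (optionally
over per-neuron mean points), apply three admission criteria, and their pin
sets are afterwards regularized from hex-lattice neighbours and missing
columns filled in by neighbour medians.

Any 3D point can then be assigned a (column, depth) pair by the globally
nearest pin point; depth is the pin-point index normalized to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .errors import (
    DegenerateColumnError,
    InfeasiblePinError,
    InsufficientDataError,
    InvalidParameterError,
    NoIntersectionError,
)
from .hexgrid import HexCoordinate

__all__ = [
    "PinParams",
    "MEDULLA",
    "LOBULA",
    "LOBULA_PLATE",
    "Plane",
    "Neuropil",
    "Pin",
    "RejectedPin",
    "trim_lateral_outliers",
    "estimate_endpoints",
    "smooth_ordered_points",
    "shortest_bounded_sublist",
    "resample_pin",
    "build_pin",
    "build_pins",
    "regularize_and_fill",
    "assign_points",
    "assign_point",
]


@dataclass(frozen=True)
class PinParams:
    """Per-neuropil pin-construction preset.

    ``f_lat``: lateral-outlier factor (step 3).  ``n_pc``: minimum subset
    size for the endpoint PCAs (step 5).  ``n_avg``: smoothing window
    neighbours (step 6).  ``n_tang``: divisor defining the maximum gap
    d_max (step 7).  ``n_samp``: points per finished pin (step 8).
    ``single_pca_endpoints``: one PCA over all points instead of separate
    top/bottom subset PCAs.  ``use_neuron_means``: run the PCAs on
    per-neuron mean positions instead of raw synapses (thin neuropils).
    ``top_from_median``: extrapolate r_top to the median of the ``n_avg``
    smallest-t points instead of a surface intersection (ridged top
    surface).  ``min_points``: admission criterion (i); pins from fewer
    points after outlier trimming are rejected.
    """

    f_lat: float
    n_pc: int
    n_avg: int
    n_tang: int
    n_samp: int
    single_pca_endpoints: bool = False
    use_neuron_means: bool = False
    top_from_median: bool = False
    min_points: int | None = None
    name: str = ""

    def __post_init__(self):
        if min(self.n_pc, self.n_avg, self.n_tang, self.n_samp) <= 0:
            raise InvalidParameterError("all pin parameters must be positive counts")
        if self.n_samp < self.n_tang + 1:
            raise InvalidParameterError("n_samp must be at least n_tang + 1")


MEDULLA = PinParams(f_lat=2.0, n_pc=800, n_avg=260, n_tang=7, n_samp=121, name="medulla")
LOBULA = PinParams(
    f_lat=1.5, n_pc=800, n_avg=37, n_tang=2, n_samp=76,
    single_pca_endpoints=True, top_from_median=True, min_points=37, name="lobula",
)
LOBULA_PLATE = PinParams(
    f_lat=1.0, n_pc=800, n_avg=56, n_tang=2, n_samp=51,
    single_pca_endpoints=True, use_neuron_means=True, min_points=56, name="lobula_plate",
)


@dataclass(frozen=True)
class Plane:
    """Analytic bounding plane given by a point and an outward normal."""

    point: np.ndarray
    normal: np.ndarray

    def intersect(self, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        d = np.asarray(direction, dtype=float)
        denom = float(n @ d)
        if abs(denom) < 1e-12:
            raise NoIntersectionError("axis is parallel to the bounding surface")
        t = float(n @ (np.asarray(self.point, dtype=float) - origin)) / denom
        return np.asarray(origin, dtype=float) + t * d


@dataclass(frozen=True)
class Neuropil:
    """A neuropil slab: name plus top and bottom bounding planes."""

    name: str
    top: Plane
    bottom: Plane

    @property
    def down(self) -> np.ndarray:
        """Unit vector pointing from the top surface toward the bottom."""
        v = np.asarray(self.bottom.point, dtype=float) - np.asarray(self.top.point, dtype=float)
        return v / np.linalg.norm(v)

    @classmethod
    def slab(cls, name: str, top_z: float, bottom_z: float) -> "Neuropil":
        return cls(
            name,
            Plane(np.array([0.0, 0.0, top_z]), np.array([0.0, 0.0, -1.0])),
            Plane(np.array([0.0, 0.0, bottom_z]), np.array([0.0, 0.0, 1.0])),
        )


@dataclass
class Pin:
    """Finished column centre line: exactly ``n_samp`` ordered points.

    Index 0 is the top of the neuropil, index n_samp - 1 the bottom.
    ``provenance`` records whether the pin was built from synapses,
    regularized from neighbours, or filled in for a missing column.
    """

    coordinate: HexCoordinate
    points: np.ndarray
    provenance: str = "built"

    @property
    def n_samp(self) -> int:
        return len(self.points)

    def depth_of(self, index: int) -> float:
        return index / (self.n_samp - 1)


@dataclass(frozen=True)
class RejectedPin:
    """Record of a column for which no pin could be built, with the reason."""

    coordinate: HexCoordinate
    reason: str


def _pca(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[0]


def _oriented_pc1(points: np.ndarray, down: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid, v = _pca(points)
    if float(v @ down) < 0:
        v = -v
    return centroid, v


def trim_lateral_outliers(
    points: np.ndarray,
    f_lat: float,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Drop points whose lateral (PC2-PC3 plane) distance exceeds f_lat * RMS.

    The lateral distance l_i is measured from the centroid in the plane
    orthogonal to PC1; the scale sigma_lat is the root-mean-square of the
    l_i.  Points with l_i > f_lat * sigma_lat look like they belong to a
    different column and are removed; perfectly collinear clouds (zero
    lateral spread) are retained in full.  ``axis`` supplies a precomputed
    (centroid, PC1) pair, e.g. from a per-neuron-mean PCA.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 points to trim lateral outliers")
    centroid, v = _pca(pts) if axis is None else axis
    rel = pts - centroid
    along = rel @ v
    lat = rel - np.outer(along, v)
    l = np.linalg.norm(lat, axis=1)
    sigma = float(np.sqrt(np.mean(l**2)))
    keep = l <= f_lat * sigma
    if not keep.any():
        raise DegenerateColumnError("all points removed by lateral trimming")
    return pts[keep]


def _t_values(points: np.ndarray, centroid: np.ndarray, pc1: np.ndarray, neuropil: Neuropil) -> np.ndarray:
    """Projection onto PC1, normalized so the top surface is -1, bottom +1."""
    s = (points - centroid) @ pc1
    s_top = float((neuropil.top.intersect(centroid, pc1) - centroid) @ pc1)
    s_bot = float((neuropil.bottom.intersect(centroid, pc1) - centroid) @ pc1)
    return -1.0 + 2.0 * (s - s_top) / (s_bot - s_top)


def estimate_endpoints(
    points: np.ndarray,
    t: np.ndarray,
    neuropil: Neuropil,
    params: PinParams,
    pca_points: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints r_top / r_bottom of a pin (step 5 and its variants).

    Default (thick-neuropil) mode runs separate PCAs on the top fraction
    (t < 0.1, or the ``n_pc`` smallest t if that fraction is too small) and
    the bottom fraction (t > 0.2, or the ``n_pc`` largest t), intersecting
    each subset's PC1 with the corresponding surface.  With
    ``single_pca_endpoints`` one PCA over all points supplies both
    intersections; with ``top_from_median`` r_top is instead the projection
    of the median of the ``n_avg`` smallest-t points onto that axis.
    ``pca_points`` overrides the points the single PCA runs on (per-neuron
    means in thin neuropils, where raw synapse spread along the column is
    comparable to the lateral spread and would tilt PC1).
    """
    pts = np.asarray(points, dtype=float)
    down = neuropil.down
    order = np.argsort(t, kind="stable")

    if params.single_pca_endpoints:
        centroid, v = _oriented_pc1(
            pts if pca_points is None else np.asarray(pca_points, dtype=float), down
        )
        r_bottom = neuropil.bottom.intersect(centroid, v)
        if params.top_from_median:
            k = min(params.n_avg, len(pts))
            med = np.median(pts[order[:k]], axis=0)
            # extrapolate the axis to the median position: nearest point on the line
            r_top = centroid + float((med - centroid) @ v) * v
        else:
            r_top = neuropil.top.intersect(centroid, v)
        return r_top, r_bottom

    top_sel = t < 0.1
    if top_sel.sum() < params.n_pc:
        top_sel = np.zeros(len(pts), dtype=bool)
        top_sel[order[: min(params.n_pc, len(pts))]] = True
    c_top, v_top = _oriented_pc1(pts[top_sel], down)
    r_top = neuropil.top.intersect(c_top, v_top)

    bot_sel = t > 0.2
    if bot_sel.sum() < params.n_pc:
        bot_sel = np.zeros(len(pts), dtype=bool)
        bot_sel[order[-min(params.n_pc, len(pts)):]] = True
    c_bot, v_bot = _oriented_pc1(pts[bot_sel], down)
    r_bottom = neuropil.bottom.intersect(c_bot, v_bot)
    return r_top, r_bottom


def smooth_ordered_points(
    points: np.ndarray, r_top: np.ndarray, r_bottom: np.ndarray, n_avg: int
) -> np.ndarray:
    """Sliding-window smoothing of the rank-ordered cloud (step 6).

    ``points`` must already be rank-ordered by t.  Each interior element is
    averaged with up to ``n_avg`` neighbours (a centred window of half-width
    n_avg // 2, truncated at the list ends); the endpoints r_top and
    r_bottom are prepended/appended and preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return np.stack([r_top, r_bottom])
    half = max(1, n_avg // 2)
    csum = np.cumsum(np.vstack([np.zeros(3), pts]), axis=0)
    n = len(pts)
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return np.vstack([r_top, smoothed, r_bottom])


def shortest_bounded_sublist(L: np.ndarray, d_max: float) -> np.ndarray:
    """Shortest order-preserving sublist with consecutive gaps <= d_max (step 7).

    The list starts at r_top (first element) and ends at r_bottom (last).
    Solved exactly by dynamic programming over the ordered list (O(n^2));
    among equally short solutions, predecessors with the earliest index are
    preferred, which makes the result deterministic.
    """
    pts = np.asarray(L, dtype=float)
    n = len(pts)
    if n < 2:
        raise InsufficientDataError("list must contain at least the two endpoints")
    steps = np.full(n, np.inf)
    steps[0] = 0.0
    prev = np.full(n, -1, dtype=int)
    for i in range(1, n):
        d = np.linalg.norm(pts[:i] - pts[i], axis=1)
        ok = (d <= d_max) & np.isfinite(steps[:i])
        if not ok.any():
            continue
        cand = np.nonzero(ok)[0]
        vals = steps[cand]
        j = cand[int(np.argmin(vals))]  # argmin -> earliest index on ties
        steps[i] = steps[j] + 1.0
        prev[i] = j
    if not np.isfinite(steps[-1]):
        raise InfeasiblePinError("no sublist satisfies the maximum-gap constraint")
    path = [n - 1]
    while path[-1] != 0:
        path.append(int(prev[path[-1]]))
    return pts[path[::-1]]


def resample_pin(
    O: np.ndarray, n_samp: int, coordinate: HexCoordinate = HexCoordinate(0, 0)
) -> Pin:
    """Uniform arc-length resampling with PCHIP interpolation (step 8).

    Each spatial coordinate is interpolated against cumulative arc length
    with a shape-preserving piecewise cubic (no overshoot beyond the data
    range of a monotone coordinate) and sampled at ``n_samp`` uniform
    arc-length stations; the endpoints are reproduced exactly.
    """
    pts = np.asarray(O, dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("need at least two points to resample")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])
    pts = pts[keep]
    if len(pts) < 2:  # fully degenerate: all points coincide
        out = np.tile(pts[0], (n_samp, 1))
        return Pin(coordinate, out)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    u = np.linspace(0.0, s[-1], n_samp)
    out = np.stack([PchipInterpolator(s, pts[:, k])(u) for k in range(3)], axis=1)
    out[0], out[-1] = pts[0], pts[-1]
    return Pin(coordinate, out)


def build_pin(
    points: np.ndarray,
    coordinate: HexCoordinate,
    neuropil: Neuropil,
    params: PinParams,
    neuron_ids: Sequence | None = None,
) -> Pin | RejectedPin:
    """Full eight-step pin construction for one column.

    Thin-neuropil presets (``min_points`` set) apply three admission
    criteria: (i) at least ``min_points`` synapses survive outlier
    trimming; (ii) the centroid of the 5% top-most points lies within
    d_max of r_top; (iii) the centroid of the 5% bottom-most points lies
    within d_max of r_bottom.  A failed criterion yields a
    :class:`RejectedPin` with the reason instead of a pin.
    """
    pts = np.asarray(points, dtype=float)
    pca_pts = pts
    if params.use_neuron_means:
        # thin neuropils: PCAs run on per-neuron mean positions (>= 3 cells),
        # the remaining steps still use the full synapse cloud
        if neuron_ids is None:
            raise InvalidParameterError("use_neuron_means requires neuron_ids")
        ids = np.asarray(neuron_ids)
        pca_pts = np.stack([pts[ids == u].mean(axis=0) for u in np.unique(ids)])
    if len(pts) < 3 or len(np.unique(pca_pts, axis=0)) < 3:
        raise InsufficientDataError(f"column {coordinate}: fewer than 3 points")

    down = neuropil.down
    centroid, pc1 = _oriented_pc1(pca_pts, down)
    kept = trim_lateral_outliers(pts, params.f_lat, axis=(centroid, pc1))
    if params.min_points is not None and len(kept) < params.min_points:
        return RejectedPin(coordinate, "criterion-i")

    t = _t_values(kept, centroid, pc1, neuropil)
    r_top, r_bottom = estimate_endpoints(kept, t, neuropil, params, pca_points=pca_pts)
    d_max = float(np.linalg.norm(r_top - r_bottom)) / params.n_tang

    if params.min_points is not None:
        order = np.argsort(t, kind="stable")
        k = max(1, int(np.ceil(0.05 * len(kept))))
        top_centroid = kept[order[:k]].mean(axis=0)
        bot_centroid = kept[order[-k:]].mean(axis=0)
        if np.linalg.norm(top_centroid - r_top) > d_max:
            return RejectedPin(coordinate, "criterion-ii")
        if np.linalg.norm(bot_centroid - r_bottom) > d_max:
            return RejectedPin(coordinate, "criterion-iii")

    ordered = kept[np.argsort(t, kind="stable")]
    L = smooth_ordered_points(ordered, r_top, r_bottom, params.n_avg)
    O = shortest_bounded_sublist(L, d_max)
    pin = resample_pin(O, params.n_samp, coordinate)
    return pin


def build_pins(
    synapses,
    neuropil: Neuropil,
    params: PinParams,
    coord_columns: tuple[str, str] = ("p", "q"),
) -> tuple[dict[HexCoordinate, Pin], list[RejectedPin]]:
    """Build pins for every column present in an assigned synapse table.

    ``synapses`` is a DataFrame with columns x, y, z, the two coordinate
    columns, and (for neuron-mean presets) ``neuron_id``.
    """
    pins: dict[HexCoordinate, Pin] = {}
    rejected: list[RejectedPin] = []
    pc, qc = coord_columns
    for (p, q), grp in synapses.groupby([pc, qc], sort=True):
        coord = HexCoordinate(int(p), int(q))
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        ids = grp["neuron_id"].to_numpy() if "neuron_id" in grp.columns else None
        try:
            result = build_pin(pts, coord, neuropil, params, neuron_ids=ids)
        except (InsufficientDataError, DegenerateColumnError, InfeasiblePinError) as exc:
            rejected.append(RejectedPin(coord, type(exc).__name__))
            continue
        if isinstance(result, RejectedPin):
            rejected.append(result)
        else:
            pins[coord] = result
    return pins, rejected


def _neighbourhood(coord: HexCoordinate, pins: Mapping[HexCoordinate, Pin], radius: int):
    return [
        pins[b]
        for b in pins
        if max(abs(b.p - coord.p), abs(b.q - coord.q)) <= radius
    ]


def regularize_and_fill(
    pins: Mapping[HexCoordinate, Pin],
    coords: Sequence[HexCoordinate] | None = None,
    max_iter: int = 10,
    radius: int = 2,
) -> dict[HexCoordinate, Pin]:
    """Iteratively regularize pins from neighbours and fill in missing ones.

    Regularization replaces each pin by the per-station median of the
    offset-from-first-point polylines of all pins whose coordinates differ
    by at most ``radius`` in either axial component (including itself),
    re-anchored at the pin's own first point.  Filling-in creates a missing
    pin as the per-station median of its four axial +/-1 neighbours, or of
    the two neighbours along one axis when the full cross is absent.  The
    loop stops when an iteration fills nothing, or at ``max_iter``.
    Columns with no qualifying neighbours stay missing.
    """
    if not pins:
        raise InsufficientDataError("at least one built pin is required")
    pins = dict(pins)
    target = sorted(coords) if coords is not None else sorted(pins)
    for _ in range(max_iter):
        new: dict[HexCoordinate, Pin] = {}
        for a, pin in pins.items():
            nbrs = _neighbourhood(a, pins, radius)
            offsets = np.stack([b.points - b.points[0] for b in nbrs])
            med = np.median(offsets, axis=0)
            # origin of a filled pin is kept through later regularization
            if pin.provenance == "filled" or len(nbrs) == 1:
                prov = pin.provenance
            else:
                prov = "regularized"
            new[a] = Pin(a, med + pin.points[0], prov)
        pins = new
        n_filled = 0
        for a in target:
            if a in pins:
                continue
            cross = [
                HexCoordinate(a.p + 1, a.q), HexCoordinate(a.p - 1, a.q),
                HexCoordinate(a.p, a.q + 1), HexCoordinate(a.p, a.q - 1),
            ]
            if all(c in pins for c in cross):
                nbrs = [pins[c] for c in cross]
            elif cross[0] in pins and cross[1] in pins:
                nbrs = [pins[cross[0]], pins[cross[1]]]
            elif cross[2] in pins and cross[3] in pins:
                nbrs = [pins[cross[2]], pins[cross[3]]]
            else:
                continue
            med = np.median(np.stack([b.points for b in nbrs]), axis=0)
            pins[a] = Pin(a, med, "filled")
            n_filled += 1
        if n_filled == 0:
            break
    still_missing = [a for a in target if a not in pins]
    if still_missing:
        warnings.warn(
            f"{len(still_missing)} column(s) could not be filled in: {still_missing[:5]}",
            stacklevel=2,
        )
    return pins


def assign_points(points: np.ndarray, pins: Mapping[HexCoordinate, Pin]):
    """Assign each point the nearest pin's column and its normalized depth.

    Depth is the index of the globally nearest pin point divided by
    (n_samp - 1).  Ties between pins go to the lexicographically lowest
    (p, q), then to the shallower station.  Returns (coords, depths).
    """
    if not pins:
        raise InsufficientDataError("no pins")
    items = sorted(pins.items())
    pool = np.concatenate([p.points for _, p in items])
    n_samps = [p.n_samp for _, p in items]
    pin_idx = np.concatenate([np.full(n, i) for i, n in enumerate(n_samps)])
    station = np.concatenate([np.arange(n) for n in n_samps])
    tree = cKDTree(pool)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return [], np.array([])
    k = min(2, len(pool))
    if k == 2:
        dist, idx = tree.query(pts, k=2)
        best = idx[:, 0].copy()
        tied = np.isclose(dist[:, 0], dist[:, 1], rtol=1e-12, atol=1e-9)
        for i in np.nonzero(tied)[0]:
            cand = tree.query_ball_point(pts[i], dist[i, 0] * (1 + 1e-12) + 1e-9)
            best[i] = min(cand, key=lambda c: (items[pin_idx[c]][0], station[c]))
    else:
        _, best = tree.query(pts, k=1)
    coords = [items[pin_idx[b]][0] for b in best]
    depths = station[best] / (np.array(n_samps)[pin_idx[best]] - 1)
    return coords, depths


def assign_point(point: np.ndarray, pins: Mapping[HexCoordinate, Pin]):
    """Single-point convenience wrapper around :func:`assign_points`."""
    coords, depths = assign_points(np.asarray(point, dtype=float)[None, :], pins)
    return coords[0], float(depths[0])
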
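"""Hexagonal column coordinates and nearest-axis neuron assignment.

Columns of the insect optic lobe repeat on a hexagonal lattice and are
addressed by axial coordinates (p, q) shared across neuropils.  Neurons are
placed on this lattice by assigning each of their synapses to the nearest
column axis (a straight proto-axis early in the bootstrap, a curved pin
later) and labelling the cell with the mode of its synapse assignments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InsufficientDataError

__all__ = [
    "HexCoordinate",
    "ProtoAxis",
    "hex_ring_distance",
    "axial_to_xy",
    "compute_proto_axis",
    "assign_synapses_to_axes",
    "assign_neuron_coordinate",
    "assign_neurons",
    "bootstrap_assignments",
]


@dataclass(frozen=True, order=True)
class HexCoordinate:
    """Axial (p, q) address of a retinotopic column.

    Ordering is lexicographic in (p, q); this is the deterministic tie-break
    used throughout the package wherever two columns are equally plausible.
    """

    p: int
    q: int

    @property
    def equator(self) -> bool:
        # Convention: the equator row is q == 0 (orientation of the axes
        # relative to the eye's horizontal/vertical axes is a convention).
        return self.q == 0


def hex_ring_distance(a: HexCoordinate, b: HexCoordinate) -> int:
    """Hex graph distance between two axial coordinates."""
    dp, dq = a.p - b.p, a.q - b.q
    return (abs(dp) + abs(dq) + abs(dp + dq)) // 2


def axial_to_xy(p, q, spacing: float = 1.0) -> np.ndarray:
    """Embed axial coordinates into the plane with the given centre spacing."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    x = spacing * (p + 0.5 * q)
    y = spacing * (np.sqrt(3.0) / 2.0) * q
    return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class ProtoAxis:
    """Straight-line column axis: centroid origin and unit direction.

    The direction is oriented from the top of the neuropil to the bottom.
    """

    coordinate: HexCoordinate
    origin: np.ndarray
    direction: np.ndarray


def compute_proto_axis(
    points: np.ndarray,
    coordinate: HexCoordinate = HexCoordinate(0, 0),
    down: Sequence[float] = (0.0, 0.0, 1.0),
) -> ProtoAxis:
    """First-principal-component axis of a synapse cloud.

    Parameters
    ----------
    points
        (n, 3) synapse positions in nm; at least three distinct points.
    down
        Reference vector pointing from the neuropil top to its bottom; the
        axis sign is chosen to have positive dot product with it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InsufficientDataError("points must be an (n, 3) array")
    if len(np.unique(pts, axis=0)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct points for a proto-axis, got {len(np.unique(pts, axis=0))}"
        )
    origin = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - origin, full_matrices=False)
    direction = vt[0]
    if float(np.dot(direction, np.asarray(down, dtype=float))) < 0:
        direction = -direction
    return ProtoAxis(coordinate, origin, direction / np.linalg.norm(direction))


def _axis_items(axes) -> list[tuple[HexCoordinate, object]]:
    """Normalize the axes argument to a lexicographically sorted item list."""
    if isinstance(axes, Mapping):
        items = [(c, a) for c, a in axes.items()]
    else:
        items = [(a.coordinate, a) for a in axes]
    return sorted(items, key=lambda it: it[0])


def assign_synapses_to_axes(points: np.ndarray, axes) -> list[HexCoordinate]:
    """Assign each 3D point to the nearest column axis or pin.

    ``axes`` is a sequence of :class:`ProtoAxis` / pin objects (anything with
    ``coordinate`` and either ``direction`` or ``points``) or a mapping from
    coordinate to axis.  Distance to a straight axis is the exact
    point-to-line distance; distance to a pin is the minimum distance to any
    of its pin points.  Exact ties go to the lowest (p, q) lexicographically.
    """
    items = _axis_items(axes)
    if not items:
        raise InsufficientDataError("no axes provided")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return []

    straight = all(hasattr(a, "direction") for _, a in items)
    if straight:
        # exact line distances, vectorized over (points x axes)
        d2 = np.empty((len(pts), len(items)))
        for j, (_, ax) in enumerate(items):
            rel = pts - ax.origin
            along = rel @ ax.direction
            d2[:, j] = np.einsum("ij,ij->i", rel, rel) - along**2
        idx = np.argmin(d2, axis=1)  # argmin takes the first (lowest) on ties
        return [items[j][0] for j in idx]

    # polyline path: pool all pin points into one KD-tree
    pools, labels = [], []
    for j, (_, pin) in enumerate(items):
        arr = np.asarray(pin.points, dtype=float)
        pools.append(arr)
        labels.append(np.full(len(arr), j))
    pool = np.concatenate(pools)
    label = np.concatenate(labels)
    tree = cKDTree(pool)
    dist, nearest = tree.query(pts, k=1)
    out = [items[label[i]][0] for i in nearest]
    # resolve exact ties deterministically (rare): re-query a ball around the
    # nearest distance and take the lexicographically lowest coordinate
    k2 = min(2, len(pool))
    if k2 == 2:
        dist2, near2 = tree.query(pts, k=2)
        tied = np.isclose(dist2[:, 0], dist2[:, 1], rtol=1e-12, atol=1e-9)
        for i in np.nonzero(tied)[0]:
            cand = tree.query_ball_point(pts[i], dist2[i, 0] * (1 + 1e-12) + 1e-9)
            out[i] = min(items[label[c]][0] for c in cand)
    return out


def assign_neuron_coordinate(
    assignments: Iterable[HexCoordinate],
) -> tuple[HexCoordinate, bool]:
    """Modal coordinate of a multiset of per-synapse (or per-pairing) votes.

    Returns ``(coordinate, ambiguous)``; the flag is set when the top two
    counts tie (ties are broken to the lowest (p, q) so downstream behaviour
    stays reproducible, but the ambiguity is surfaced rather than resolved by
    manual inspection).
    """
    counts = Counter(assignments)
    if not counts:
        raise InsufficientDataError("empty assignment multiset")
    top = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == top)
    return winners[0], len(winners) > 1


def assign_neurons(synapses: pd.DataFrame, axes) -> pd.DataFrame:
    """Per-neuron coordinate table from a synapse table and a set of axes.

    ``synapses`` needs columns ``neuron_id, x, y, z``.  Returns a frame
    indexed by neuron id with columns ``p, q, ambiguous``.
    """
    pts = synapses[["x", "y", "z"]].to_numpy(dtype=float)
    coords = assign_synapses_to_axes(pts, axes)
    per_syn = pd.DataFrame(
        {"neuron_id": synapses["neuron_id"].to_numpy(), "coord": coords}
    )
    rows = {}
    for nid, grp in per_syn.groupby("neuron_id", sort=True):
        coord, amb = assign_neuron_coordinate(grp["coord"])
        rows[nid] = (coord.p, coord.q, amb)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["p", "q", "ambiguous"])
    out.index.name = "neuron_id"
    return out


def bootstrap_assignments(
    synapses: pd.DataFrame,
    seed_axes,
    n_iter: int = 3,
    down: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[pd.DataFrame, list[ProtoAxis]]:
    """Iterative assign -> rebuild-axes -> reassign loop.

    The study bootstrapped column addresses in stages (manual seed columns,
    straight proto-axes, prototype pins); here the stages collapse into one
    loop that alternates nearest-axis assignment with axis re-estimation from
    the currently assigned synapses.  ``seed_axes`` provides the initial
    scaffold (e.g. planted lattice axes or axes from a seed cell type).
    """
    axes = seed_axes
    assignment = None
    for _ in range(max(1, n_iter)):
        assignment = assign_neurons(synapses, axes)
        merged = synapses.merge(
            assignment[["p", "q"]], left_on="neuron_id", right_index=True
        )
        new_axes = []
        for (p, q), grp in merged.groupby(["p", "q"], sort=True):
            pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
            if len(np.unique(pts, axis=0)) < 3:
                continue
            new_axes.append(
                compute_proto_axis(pts, HexCoordinate(int(p), int(q)), down=down)
            )
        if new_axes:
            axes = new_axes
    return assignment, list(axes) if not isinstance(axes, Mapping) else list(axes.values())
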
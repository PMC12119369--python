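"""Anchor-candidate assignment by normalized maximum-weight matching.

Used to hand the hexagonal coordinates of anchor neurons (Mi1-like) down to
candidate neurons (T4-like) that innervate a different neuropil: the
anchor-to-candidate connection matrix is row-normalized (each anchor's
connections divided by its total to the candidate class, removing regional
synapse-density bias), a one-to-one assignment maximizing total normalized
weight is solved globally, and assignments whose anchor and candidate mean
synapse positions lie farther apart than a distance threshold (default
8 um, about one column spacing at the relevant depth) are vetoed.
Per-anchor groups that keep enough close candidates across the candidate
classes supply the seed points for building pins in the target neuropil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import InvalidParameterError

__all__ = [
    "DEFAULT_DISTANCE_THRESHOLD_NM",
    "normalize_rows",
    "max_weight_assignment",
    "veto_by_distance",
    "Group",
    "form_groups",
]

DEFAULT_DISTANCE_THRESHOLD_NM = 8_000.0  # 8 um


def normalize_rows(C: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows stay zero (with a warning)."""
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        raise InvalidParameterError("connection counts must be nonnegative")
    sums = C.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero row(s) left unnormalized", stacklevel=2)
    out = np.divide(C, sums, out=np.zeros_like(C), where=sums > 0)
    return out


def max_weight_assignment(C: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one (partial, rectangular allowed) matching maximizing total weight.

    Solved globally with the Hungarian algorithm; rows and columns are used
    in their given order, which after a lexicographic pre-sort of the
    inputs makes ties deterministic.
    """
    C = np.asarray(C, dtype=float)
    if not np.isfinite(C).all():
        raise InvalidParameterError("matrix must be finite")
    rows, cols = linear_sum_assignment(C, maximize=True)
    return sorted(zip(rows.tolist(), cols.tolist()))


def veto_by_distance(
    pairs,
    anchor_positions: np.ndarray | dict,
    candidate_positions: np.ndarray | dict,
    threshold: float = DEFAULT_DISTANCE_THRESHOLD_NM,
) -> tuple[list, list]:
    """Split matched pairs into accepted and rejected by spatial distance.

    The distance compares the anchor's mean presynapse position (toward the
    candidate class) with the candidate's mean postsynapse position; a pair
    is kept iff it does not exceed ``threshold`` (nm).  Pairs with a missing
    position are rejected with reason ``missing-position``.  Returns
    (accepted as (anchor, candidate, distance), rejected as
    (anchor, candidate, reason)).
    """
    accepted, rejected = [], []
    for a, c in pairs:
        try:
            pa = np.asarray(anchor_positions[a], dtype=float)
            pc = np.asarray(candidate_positions[c], dtype=float)
        except (KeyError, IndexError):
            rejected.append((a, c, "missing-position"))
            continue
        if np.isnan(pa).any() or np.isnan(pc).any():
            rejected.append((a, c, "missing-position"))
            continue
        d = float(np.linalg.norm(pa - pc))
        if d <= threshold:
            accepted.append((a, c, d))
        else:
            rejected.append((a, c, "too-far"))
    return accepted, rejected


@dataclass
class Group:
    """Valid per-anchor candidate group with the seed points it contributes."""

    anchor: object
    members: dict  # candidate class -> candidate id
    points: np.ndarray  # (k, 3) positions of the close candidates, k >= 3


def form_groups(
    assignments: pd.DataFrame,
    candidate_positions: dict,
    n_classes: int = 4,
    min_close: int = 3,
) -> list[Group]:
    """Collect per-anchor candidate groups across independently matched classes.

    ``assignments`` has columns anchor, cls, candidate, accepted (one
    matching per candidate class).  A group is valid when the anchor has an
    assignment in every class and at least ``min_close`` of them survived
    the distance veto; the accepted candidates' positions (looked up by
    (cls, candidate)) become the group's seed points.
    """
    groups = []
    for anchor, grp in assignments.groupby("anchor", sort=True):
        if grp["cls"].nunique() < n_classes:
            continue
        close = grp[grp["accepted"]]
        if len(close) < min_close:
            continue
        members = dict(zip(grp["cls"], grp["candidate"]))
        pts = np.stack(
            [np.asarray(candidate_positions[(r.cls, r.candidate)], dtype=float)
             for r in close.itertuples()]
        )
        groups.append(Group(anchor, members, pts))
    return groups
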
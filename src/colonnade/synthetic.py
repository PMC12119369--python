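"""Synthetic optic-lobe volumes with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a hexagonal lattice of columns with (optionally curved) centre
axes spanning a neuropil slab, per-type synapse clouds whose depths follow
planted profiles along those axes with small lateral jitter, planted
type-to-type connectivity rules with Poisson count noise, and per-synapse
transmitter probability vectors concentrated on the true transmitter.

Every quantity the analysis modules recover (home column, depth, type,
transmitter, coverage) is recorded as ground truth alongside the tables,
so recovery can be scored exactly.  All randomness flows from explicit
seeds; regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidSpecError
from .hexgrid import HexCoordinate, axial_to_xy, hex_ring_distance

__all__ = [
    "TRANSMITTERS",
    "PartnerRule",
    "TypeSpec",
    "HexGrid",
    "SyntheticVolume",
    "generate_grid",
    "generate_neurons",
    "generate_connectivity",
    "generate_volume",
    "default_specs",
    "default_volume",
    "write_volume",
]

TRANSMITTERS = ("ACh", "Glu", "GABA", "His", "Dop", "OA", "5HT")

#: default slab thickness (nm), comparable to the ~40 um medulla depth
DEFAULT_DEPTH_NM = 40_000.0
#: default centre-to-centre column spacing (nm), ~5 um as in the medulla
DEFAULT_SPACING_NM = 5_000.0


@dataclass(frozen=True)
class PartnerRule:
    """Planted connectivity rule: mean connections per cell to a partner type."""

    partner: str
    direction: str  # "out" (this type -> partner) or "in" (partner -> this type)
    mean: float

    def __post_init__(self):
        if self.direction not in ("out", "in"):
            raise InvalidSpecError(f"direction must be 'out' or 'in', got {self.direction!r}")
        if self.mean < 0:
            raise InvalidSpecError("rule mean must be nonnegative")


@dataclass(frozen=True)
class TypeSpec:
    """Specification of one synthetic cell type.

    ``depth_profile_pre``/``_post`` are lists of (depth in [0,1], relative
    density) control points; densities are interpolated linearly, must be
    nonnegative and normalizable.  ``columns_per_cell`` > 1 plants a
    multicolumnar type whose synapses spread over the home column and its
    nearest neighbours.
    """

    name: str
    n_cells: int
    columns_per_cell: int = 1
    depth_profile_pre: Sequence[tuple[float, float]] = ((0.0, 1.0), (1.0, 1.0))
    depth_profile_post: Sequence[tuple[float, float]] = ((0.0, 1.0), (1.0, 1.0))
    partner_rules: Sequence[PartnerRule] = ()
    transmitter: str = "ACh"
    n_pre: int = 120
    n_post: int = 180

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidSpecError(f"{self.name}: n_cells must be >= 1")
        if self.columns_per_cell < 1:
            raise InvalidSpecError(f"{self.name}: columns_per_cell must be >= 1")
        if self.transmitter not in TRANSMITTERS:
            raise InvalidSpecError(f"{self.name}: unknown transmitter {self.transmitter!r}")
        for prof in (self.depth_profile_pre, self.depth_profile_post):
            dens = np.array([d for _, d in prof], dtype=float)
            if (dens < 0).any() or dens.sum() <= 0:
                raise InvalidSpecError(
                    f"{self.name}: depth profile densities must be nonnegative and normalizable"
                )


@dataclass
class HexGrid:
    """Hex lattice of columns with planted centre axes.

    ``axes`` maps each coordinate to an (n, 3) polyline from the top surface
    (z = 0) to the bottom surface (z = depth).
    """

    coords: list[HexCoordinate]
    axes: dict[HexCoordinate, np.ndarray]
    spacing: float
    depth: float
    curvature: float = 0.0

    @property
    def n_columns(self) -> int:
        return len(self.coords)

    def axis_point(self, coord: HexCoordinate, t: np.ndarray) -> np.ndarray:
        """Interpolate the planted axis of ``coord`` at depth fraction t."""
        poly = self.axes[coord]
        s = np.linspace(0.0, 1.0, len(poly))
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack([np.interp(t, s, poly[:, k]) for k in range(3)], axis=1)


@dataclass
class SyntheticVolume:
    """A generated dataset: tables plus the ground truth that produced them."""

    grid: HexGrid
    specs: list[TypeSpec]
    neurons: pd.DataFrame
    synapses: pd.DataFrame
    connections: pd.DataFrame
    seed: int


def generate_grid(
    n_rings: int,
    spacing: float = DEFAULT_SPACING_NM,
    curvature: float = 0.0,
    depth: float = DEFAULT_DEPTH_NM,
    n_axis_points: int = 61,
) -> HexGrid:
    """Hexagonal lattice of ``n_rings`` rings around a centre column.

    Each coordinate carries a planted centre line from the top surface
    (z = 0) to the bottom surface (z = depth).  ``curvature`` (1/nm) bends
    every axis into a circular arc in the x-z plane; 0 keeps them straight
    and parallel.  Ring 1 has 7 coordinates, ring 2 has 19, ring n has
    1 + 3 n (n + 1).
    """
    if spacing <= 0:
        raise InvalidParameterError(f"spacing must be positive, got {spacing}")
    if n_rings < 1:
        raise InvalidParameterError(f"n_rings must be >= 1, got {n_rings}")
    if depth <= 0:
        raise InvalidParameterError("depth must be positive")
    if curvature < 0 or (curvature > 0 and 1.0 / curvature < depth / 2.0):
        raise InvalidParameterError("curvature radius must be at least half the depth")

    origin = HexCoordinate(0, 0)
    coords = sorted(
        HexCoordinate(p, q)
        for p in range(-n_rings, n_rings + 1)
        for q in range(-n_rings, n_rings + 1)
        if hex_ring_distance(HexCoordinate(p, q), origin) <= n_rings
    )

    t = np.linspace(0.0, 1.0, n_axis_points)
    if curvature > 0:
        radius = 1.0 / curvature
        half = depth / 2.0
        # circular arc through top and bottom, sagitta toward +x at mid-depth
        bend = np.sqrt(radius**2 - (depth * (t - 0.5)) ** 2) - np.sqrt(radius**2 - half**2)
    else:
        bend = np.zeros_like(t)

    axes = {}
    for c in coords:
        xy = axial_to_xy(c.p, c.q, spacing)
        poly = np.empty((n_axis_points, 3))
        poly[:, 0] = xy[0] + bend
        poly[:, 1] = xy[1]
        poly[:, 2] = t * depth
        axes[c] = poly
    return HexGrid(coords, axes, spacing, depth, curvature)


def _profile_sampler(profile, rng, n, grid_points: int = 512) -> np.ndarray:
    """Sample depths from a piecewise-linear density given as control points."""
    prof = sorted((float(d), float(w)) for d, w in profile)
    xs = np.array([d for d, _ in prof])
    ws = np.array([w for _, w in prof])
    g = np.linspace(0.0, 1.0, grid_points)
    dens = np.interp(g, xs, ws, left=0.0, right=0.0)
    if dens.sum() <= 0:
        dens = np.ones_like(g)
    p = dens / dens.sum()
    idx = rng.choice(grid_points, size=n, p=p)
    # uniform offset within a grid cell keeps the sample continuous
    step = 1.0 / (grid_points - 1)
    return np.clip(g[idx] + rng.uniform(-step / 2, step / 2, size=n), 0.0, 1.0)


def _cell_columns(grid: HexGrid, home: HexCoordinate, k: int) -> list[HexCoordinate]:
    """Home column plus the k-1 nearest lattice columns (deterministic)."""
    if k == 1:
        return [home]
    hx = axial_to_xy(home.p, home.q, grid.spacing)
    ranked = sorted(
        grid.coords,
        key=lambda c: (float(np.linalg.norm(axial_to_xy(c.p, c.q, grid.spacing) - hx)), c),
    )
    return ranked[:k]


def generate_neurons(
    specs: Sequence[TypeSpec],
    grid: HexGrid,
    seed: int,
    jitter_sigma: float | None = None,
) -> SyntheticVolume:
    """Plant neurons and their synapse clouds on the lattice.

    Each neuron gets a home coordinate (one neuron per column for a mosaic
    when ``n_cells`` does not exceed the column count, sampled with
    replacement otherwise) plus extra nearby columns when
    ``columns_per_cell`` > 1.  Synapse depths are drawn from the planted
    profiles; lateral jitter is isotropic Gaussian in the plane orthogonal
    to the local axis tangent with sigma = spacing / 6 by default, so
    nearest-axis assignment is almost always correct.
    """
    if not specs:
        raise InvalidSpecError("specs must be non-empty")
    known = {s.name for s in specs}
    for s in specs:
        for rule in s.partner_rules:
            if rule.partner not in known:
                raise InvalidSpecError(
                    f"{s.name}: partner rule names unknown type {rule.partner!r}"
                )
    if jitter_sigma is None:
        jitter_sigma = grid.spacing / 6.0

    rng = np.random.default_rng(seed)
    neuron_rows = []
    syn_rows = []
    next_id = 1
    sorted_coords = sorted(grid.coords)

    for spec in specs:
        if spec.n_cells <= grid.n_columns:
            homes = [sorted_coords[i] for i in rng.permutation(grid.n_columns)[: spec.n_cells]]
        else:
            homes = [sorted_coords[i] for i in rng.integers(0, grid.n_columns, spec.n_cells)]
        for home in homes:
            nid = next_id
            next_id += 1
            cols = _cell_columns(grid, home, spec.columns_per_cell)
            soma_xy = axial_to_xy(home.p, home.q, grid.spacing)
            neuron_rows.append(
                {
                    "neuron_id": nid,
                    "type": spec.name,
                    "instance": f"{spec.name}_R",
                    "soma_x": soma_xy[0],
                    "soma_y": soma_xy[1],
                    "soma_z": -grid.depth / 8.0,
                    "true_type": spec.name,
                    "home_p": home.p,
                    "home_q": home.q,
                    "transmitter": spec.transmitter,
                }
            )
            for polarity, n_syn, profile in (
                ("pre", spec.n_pre, spec.depth_profile_pre),
                ("post", spec.n_post, spec.depth_profile_post),
            ):
                if n_syn == 0:
                    continue
                depths = _profile_sampler(profile, rng, n_syn)
                col_idx = rng.integers(0, len(cols), n_syn)
                conf = rng.uniform(0.5, 1.0, n_syn)
                low = rng.random(n_syn) < 0.05
                conf[low] = rng.uniform(0.1, 0.5, low.sum())
                gauss = rng.normal(0.0, jitter_sigma, (n_syn, 2))
                pos = np.empty((n_syn, 3))
                for ci, col in enumerate(cols):
                    sel = col_idx == ci
                    if not sel.any():
                        continue
                    d = depths[sel]
                    base = grid.axis_point(col, d)
                    poly = grid.axes[col]
                    j = np.minimum((d * (len(poly) - 1)).astype(int), len(poly) - 2)
                    tang = poly[j + 1] - poly[j]
                    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
                    helper = np.tile([1.0, 0.0, 0.0], (len(d), 1))
                    swap = np.abs(tang @ np.array([1.0, 0.0, 0.0])) > 0.9
                    helper[swap] = [0.0, 1.0, 0.0]
                    u = np.cross(tang, helper)
                    u /= np.linalg.norm(u, axis=1, keepdims=True)
                    v = np.cross(tang, u)
                    pos[sel] = base + gauss[sel, :1] * u + gauss[sel, 1:] * v
                probs = None
                if polarity == "pre":
                    probs = np.stack([_nt_probs(spec.transmitter, rng) for _ in range(n_syn)])
                for k in range(n_syn):
                    col = cols[col_idx[k]]
                    row = {
                        "neuron_id": nid,
                        "polarity": polarity,
                        "x": pos[k, 0],
                        "y": pos[k, 1],
                        "z": pos[k, 2],
                        "confidence": conf[k],
                        "true_p": col.p,
                        "true_q": col.q,
                        "true_depth": depths[k],
                    }
                    if probs is not None:
                        for name, pr in zip(TRANSMITTERS, probs[k]):
                            row[f"nt_{name}"] = pr
                    syn_rows.append(row)

    neurons = pd.DataFrame(neuron_rows)
    synapses = pd.DataFrame(syn_rows)
    for name in TRANSMITTERS:
        col = f"nt_{name}"
        if col not in synapses.columns:
            synapses[col] = np.nan
    connections = pd.DataFrame(columns=["pre_id", "post_id", "weight", "region"])
    return SyntheticVolume(grid, list(specs), neurons, synapses, connections, seed)


def _nt_probs(true_nt: str, rng) -> np.ndarray:
    """Probability vector concentrated on the true transmitter.

    10% of presynapses get their mass put on a random wrong class, emulating
    classifier error; the winning class receives 0.55-0.95 of the mass.
    """
    k = len(TRANSMITTERS)
    target = TRANSMITTERS.index(true_nt)
    if rng.random() < 0.10:
        target = int(rng.integers(0, k))
    w = rng.uniform(0.55, 0.95)
    rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - w)
    probs = np.empty(k)
    probs[target] = w
    probs[np.arange(k) != target] = rest
    return probs


def generate_connectivity(
    volume: SyntheticVolume, specs: Sequence[TypeSpec] | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw the connection table from the planted partner rules.

    For each rule, every cell of the rule's own type draws a Poisson total
    around the stated mean and distributes it over its three spatially
    nearest partner cells (by home-column distance), preferring the closest.
    The resulting table replaces ``volume.connections`` and is returned.
    """
    specs = list(specs) if specs is not None else volume.specs
    seed = volume.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)

    neurons = volume.neurons
    by_type = {t: g for t, g in neurons.groupby("true_type")}
    home_xy = {
        int(r.neuron_id): axial_to_xy(r.home_p, r.home_q, volume.grid.spacing)
        for r in neurons.itertuples()
    }
    rows = []
    for spec in specs:
        if spec.name not in by_type:
            continue
        own = by_type[spec.name]
        for rule in spec.partner_rules:
            partners = by_type.get(rule.partner)
            if partners is None or rule.mean == 0:
                continue
            pids = partners["neuron_id"].to_numpy()
            pxy = np.stack([home_xy[int(i)] for i in pids])
            for nid in own["neuron_id"].to_numpy():
                total = rng.poisson(rule.mean)
                if total == 0:
                    continue
                dist = np.linalg.norm(pxy - home_xy[int(nid)], axis=1)
                order = np.argsort(dist, kind="stable")[:3]
                share = np.array([0.6, 0.25, 0.15][: len(order)])
                share = share / share.sum()
                counts = rng.multinomial(total, share)
                for j, cnt in zip(order, counts):
                    if cnt == 0:
                        continue
                    pre, post = (
                        (int(nid), int(pids[j]))
                        if rule.direction == "out"
                        else (int(pids[j]), int(nid))
                    )
                    rows.append({"pre_id": pre, "post_id": post, "weight": int(cnt), "region": "ME_R"})
    if rows:
        conn = (
            pd.DataFrame(rows)
            .groupby(["pre_id", "post_id", "region"], as_index=False)["weight"]
            .sum()[["pre_id", "post_id", "weight", "region"]]
        )
    else:
        conn = pd.DataFrame(columns=["pre_id", "post_id", "weight", "region"])
    volume.connections = conn
    return conn


def generate_volume(
    specs: Sequence[TypeSpec],
    seed: int,
    n_rings: int = 3,
    spacing: float = DEFAULT_SPACING_NM,
    curvature: float = 0.0,
    depth: float = DEFAULT_DEPTH_NM,
    jitter_sigma: float | None = None,
) -> SyntheticVolume:
    """Grid + neurons + connectivity in one call."""
    grid = generate_grid(n_rings, spacing, curvature, depth)
    vol = generate_neurons(specs, grid, seed, jitter_sigma=jitter_sigma)
    generate_connectivity(vol)
    return vol


def default_specs(n_cells: int = 37) -> list[TypeSpec]:
    """The standard five-type study scenario.

    Four strictly columnar types tile every column (coverage factor 1) with
    single-layer-like depth profiles at distinct depths; one multicolumnar
    type covers five columns per cell over the full lattice (coverage
    factor 5).  Partner rules are disjoint so the types are separable by
    connectivity alone; transmitters cover cholinergic, glutamatergic,
    GABAergic, aminergic (dopamine) and histaminergic cases.
    """
    narrow = lambda c: ((max(0.0, c - 0.08), 0.0), (c, 1.0), (min(1.0, c + 0.08), 0.0))
    n = n_cells
    return [
        # shallow type arborizing from the very top surface (like M1 inputs)
        TypeSpec(
            "ColA", n, 1, ((0.0, 0.6), (0.10, 1.0), (0.20, 0.0)), narrow(0.30),
            (PartnerRule("ColB", "out", 10.0),), "ACh",
        ),
        TypeSpec(
            "ColB", n, 1, narrow(0.40), narrow(0.50),
            (PartnerRule("ColC", "out", 8.0),), "Glu",
        ),
        TypeSpec(
            "ColC", n, 1, narrow(0.70), narrow(0.62),
            (PartnerRule("Ov5", "out", 6.0),), "GABA",
        ),
        # multicolumnar amacrine-like type spanning the full depth
        TypeSpec(
            "Ov5", n, 5, ((0.0, 0.5), (0.5, 1.0), (1.0, 0.5)),
            ((0.0, 0.5), (0.5, 1.0), (1.0, 0.5)),
            (PartnerRule("ColD", "out", 6.0),), "Dop",
            n_pre=200, n_post=200,
        ),
        # deep type reaching the bottom surface
        TypeSpec(
            "ColD", n, 1, ((0.80, 0.0), (0.90, 1.0), (1.0, 0.6)), narrow(0.80),
            (PartnerRule("ColA", "out", 4.0),), "His",
        ),
    ]


def default_volume(seed: int = 0, n_rings: int = 3) -> SyntheticVolume:
    """Default study volume: 3 hex rings (37 columns), 5 planted types.

    Smaller grids keep the same per-column synapse density: each type gets
    one cell per column.
    """
    n_columns = 1 + 3 * n_rings * (n_rings + 1)
    return generate_volume(default_specs(n_columns), seed, n_rings=n_rings)


def write_volume(volume: SyntheticVolume, out_dir) -> dict[str, Path]:
    """Write the three tables plus the grid axes as CSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "neurons": out / "neurons.csv",
        "synapses": out / "synapses.csv",
        "connections": out / "connections.csv",
        "grid": out / "grid.csv",
    }
    volume.neurons.to_csv(paths["neurons"], index=False)
    volume.synapses.to_csv(paths["synapses"], index=False)
    volume.connections.to_csv(paths["connections"], index=False)
    grid_rows = []
    for c in volume.grid.coords:
        for i, pt in enumerate(volume.grid.axes[c]):
            grid_rows.append(
                {"p": c.p, "q": c.q, "point_index": i, "x": pt[0], "y": pt[1], "z": pt[2]}
            )
    pd.DataFrame(grid_rows).to_csv(paths["grid"], index=False)
    return paths
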
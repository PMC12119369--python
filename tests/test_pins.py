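"""Pin construction: outlier trimming, endpoints, smoothing, the shortest
bounded sublist (against a brute-force oracle), resampling, regularization
and point-to-(column, depth) assignment."""

from itertools import combinations

import numpy as np
import pytest

from colonnade.errors import (
    DegenerateColumnError,
    InfeasiblePinError,
    InsufficientDataError,
)
from colonnade.hexgrid import HexCoordinate
from colonnade.pins import (
    LOBULA,
    LOBULA_PLATE,
    MEDULLA,
    Neuropil,
    Pin,
    RejectedPin,
    assign_point,
    assign_points,
    build_pin,
    estimate_endpoints,
    regularize_and_fill,
    resample_pin,
    shortest_bounded_sublist,
    smooth_ordered_points,
    trim_lateral_outliers,
)
from colonnade.synthetic import DEFAULT_DEPTH_NM

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------- trimming

def test_far_outlier_dropped_cluster_kept():
    cluster = RNG.normal(0.0, 1.0, (200, 3)) + [0, 0, 50]
    cluster[:, 2] = np.linspace(0, 100, 200)  # elongated along z
    outlier = np.array([[200.0, 0.0, 50.0]])  # ~10 sigma lateral
    pts = np.vstack([cluster, outlier])
    kept = trim_lateral_outliers(pts, f_lat=2.0)
    assert len(kept) >= 190
    assert not any(np.allclose(k, outlier[0]) for k in kept)


def test_huge_f_lat_keeps_everything():
    pts = RNG.normal(0.0, 5.0, (50, 3))
    kept = trim_lateral_outliers(pts, f_lat=1e6)
    assert len(kept) == 50


def test_collinear_points_all_retained():
    pts = np.array([[0.0, 0.0, z] for z in range(10)])
    kept = trim_lateral_outliers(pts, f_lat=1.0)
    assert len(kept) == 10


# ---------------------------------------------------------------- endpoints

def test_straight_vertical_cloud_endpoints_on_surfaces():
    neuropil = Neuropil.slab("m", 0.0, 1.0)
    pts = np.column_stack([
        RNG.normal(3.0, 0.01, 2000),
        RNG.normal(4.0, 0.01, 2000),
        RNG.uniform(0.0, 1.0, 2000),
    ])
    down = neuropil.down
    from colonnade.pins import _oriented_pc1, _t_values

    centroid, pc1 = _oriented_pc1(pts, down)
    t = _t_values(pts, centroid, pc1, neuropil)
    r_top, r_bottom = estimate_endpoints(pts, t, neuropil, MEDULLA)
    assert r_top[2] == pytest.approx(0.0, abs=1e-9)
    assert r_bottom[2] == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(r_top[:2], [3.0, 4.0], atol=0.05)
    assert np.allclose(r_bottom[:2], [3.0, 4.0], atol=0.05)


# ---------------------------------------------------------------- smoothing

def test_smoothing_constant_points_is_identity():
    pts = np.tile([[1.0, 2.0, 3.0]], (20, 1))
    out = smooth_ordered_points(pts, pts[0], pts[0], n_avg=6)
    assert np.allclose(out, [1.0, 2.0, 3.0])


def test_smoothing_preserves_endpoints_and_reduces_noise():
    n = 2000
    z = np.linspace(0, 1, n)
    noise = RNG.normal(0, 0.1, (n, 3))
    pts = np.column_stack([np.zeros(n), np.zeros(n), z]) + noise
    r_top, r_bottom = np.array([0.0, 0, 0]), np.array([0.0, 0, 1])
    out = smooth_ordered_points(pts, r_top, r_bottom, n_avg=260)
    assert np.array_equal(out[0], r_top) and np.array_equal(out[-1], r_bottom)
    lateral = np.abs(out[1:-1, :2])
    # averaging ~260 points shrinks the noise roughly by sqrt(window)
    assert lateral.mean() < 0.1 / np.sqrt(260) * 5


# ------------------------------------------------- shortest bounded sublist

def brute_force_shortest_length(pts: np.ndarray, d_max: float) -> int | None:
    """Exhaustive minimum-length order-preserving sublist (oracle)."""
    n = len(pts)
    for k in range(2, n + 1):
        for mid in combinations(range(1, n - 1), k - 2):
            idx = (0, *mid, n - 1)
            gaps = [np.linalg.norm(pts[idx[i + 1]] - pts[idx[i]]) for i in range(k - 1)]
            if max(gaps) <= d_max:
                return k
    return None


def test_equally_spaced_collinear_points_forced_count():
    # 99 points -> 98 intervals; d_max = span/7 allows steps of exactly 14
    pts = np.column_stack([np.zeros(99), np.zeros(99), np.linspace(0, 98, 99)])
    out = shortest_bounded_sublist(pts, d_max=98.0 / 7)
    assert len(out) == 8
    # 101 points (100 intervals): span/7 is not an integer step, min is 9
    # 101 points (100 intervals): span/7 is not an integer multiple of the
    # point spacing, so 8 points are infeasible and the minimum is 9
    pts = np.column_stack([np.zeros(101), np.zeros(101), np.linspace(0, 100, 101)])
    out = shortest_bounded_sublist(pts, d_max=100.0 / 7)
    assert len(out) == 9


def test_sublist_matches_exhaustive_oracle_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(40):
        n = rng.integers(4, 15)
        pts = np.cumsum(rng.uniform(0.2, 1.0, (n, 3)), axis=0)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        d_max = gaps.max() * rng.uniform(1.0, 2.5)
        out = shortest_bounded_sublist(pts, d_max)
        assert len(out) == brute_force_shortest_length(pts, d_max)
        # solution is a valid bounded chain with the exact endpoints
        assert np.array_equal(out[0], pts[0]) and np.array_equal(out[-1], pts[-1])
        assert np.linalg.norm(np.diff(out, axis=0), axis=1).max() <= d_max + 1e-12


def test_unbridgeable_gap_is_infeasible():
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
    with pytest.raises(InfeasiblePinError):
        shortest_bounded_sublist(pts, d_max=1.0)


# ---------------------------------------------------------------- resampling

def test_resampling_a_straight_segment_is_uniform():
    O = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 3.0], [0.0, 0.0, 10.0]])
    pin = resample_pin(O, n_samp=11)
    assert pin.n_samp == 11
    assert np.allclose(pin.points[:, 2], np.linspace(0, 10, 11))
    assert np.allclose(pin.points[:, :2], 0.0)


@pytest.mark.parametrize("params", [MEDULLA, LOBULA, LOBULA_PLATE])
def test_preset_sample_counts(params):
    O = np.column_stack([np.zeros(9), np.zeros(9), np.linspace(0, 100, 9)])
    pin = resample_pin(O, n_samp=params.n_samp)
    assert pin.n_samp == params.n_samp


def test_pchip_resampling_does_not_overshoot_monotone_coordinates():
    s = np.linspace(0, 4 * np.pi, 40)
    helix = np.column_stack([np.cos(s), np.sin(s), s])  # z monotone
    pin = resample_pin(helix, n_samp=200)
    assert pin.points[:, 2].min() >= helix[:, 2].min() - 1e-9
    assert pin.points[:, 2].max() <= helix[:, 2].max() + 1e-9
    assert (np.diff(pin.points[:, 2]) >= -1e-9).all()


# ---------------------------------------------------------------- build_pin

def _column_cloud(n=3000, jitter=800.0, seed=5):
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, DEFAULT_DEPTH_NM, n)
    x = rng.normal(0.0, jitter, n)
    y = rng.normal(0.0, jitter, n)
    return np.column_stack([x, y, z])


def test_built_pin_tracks_the_planted_straight_axis(medulla):
    pts = _column_cloud()
    pin = build_pin(pts, HexCoordinate(0, 0), medulla, MEDULLA)
    assert isinstance(pin, Pin) and pin.n_samp == 121
    # planted axis is the z axis through the origin
    lateral = np.linalg.norm(pin.points[:, :2], axis=1)
    assert lateral.max() < 5000.0 / 10


def test_pin_depth_order_is_monotone_along_the_axis(medulla):
    pts = _column_cloud(seed=6)
    pin = build_pin(pts, HexCoordinate(0, 0), medulla, MEDULLA)
    z = pin.points[:, 2]
    assert (np.diff(z) > 0).all()


def test_pin_spacing_is_uniform_in_arc_length(medulla):
    pts = _column_cloud(seed=8)
    pin = build_pin(pts, HexCoordinate(0, 0), medulla, MEDULLA)
    seg = np.linalg.norm(np.diff(pin.points, axis=0), axis=1)
    assert seg.std() / seg.mean() < 0.01


def test_thin_neuropil_point_count_criterion_rejects(medulla):
    pts = _column_cloud(n=10)
    out = build_pin(pts, HexCoordinate(0, 0), medulla, LOBULA)
    assert isinstance(out, RejectedPin) and out.reason == "criterion-i"


def test_build_pin_is_deterministic(medulla):
    pts = _column_cloud(seed=9)
    a = build_pin(pts, HexCoordinate(0, 0), medulla, MEDULLA)
    b = build_pin(pts, HexCoordinate(0, 0), medulla, MEDULLA)
    assert np.array_equal(a.points, b.points)


# ------------------------------------------------------ regularize and fill

def _straight_pin(coord, spacing=5000.0, n_samp=21):
    from colonnade.hexgrid import axial_to_xy

    xy = axial_to_xy(coord.p, coord.q, spacing)
    pts = np.column_stack([
        np.full(n_samp, xy[0]), np.full(n_samp, xy[1]),
        np.linspace(0, DEFAULT_DEPTH_NM, n_samp),
    ])
    return Pin(coord, pts)


def _lattice(n=2):
    from colonnade.hexgrid import hex_ring_distance

    coords = [HexCoordinate(p, q) for p in range(-n, n + 1) for q in range(-n, n + 1)
              if hex_ring_distance(HexCoordinate(p, q), HexCoordinate(0, 0)) <= n]
    return {c: _straight_pin(c) for c in coords}


def test_translation_identical_pins_are_a_fixed_point():
    pins = _lattice()
    out = regularize_and_fill(pins, coords=list(pins))
    for c in pins:
        assert np.allclose(out[c].points, pins[c].points)


def test_deleted_pin_is_filled_near_the_original():
    pins = _lattice()
    missing = HexCoordinate(0, 0)
    original = pins.pop(missing)
    out = regularize_and_fill(pins, coords=list(pins) + [missing])
    assert missing in out and out[missing].provenance == "filled"
    assert np.abs(out[missing].points - original.points).max() < 5000.0 / 10


def test_isolated_missing_column_stays_missing():
    pins = {HexCoordinate(0, 0): _straight_pin(HexCoordinate(0, 0))}
    far = HexCoordinate(10, 10)
    with pytest.warns(UserWarning, match="could not be filled"):
        out = regularize_and_fill(pins, coords=[HexCoordinate(0, 0), far])
    assert far not in out


# ------------------------------------------------------------- assign_point

def test_depth_endpoints_and_partition():
    pins = _lattice(1)
    some = pins[HexCoordinate(0, 0)]
    coord, depth = assign_point(some.points[0], pins)
    assert coord == HexCoordinate(0, 0) and depth == 0.0
    coord, depth = assign_point(some.points[-1], pins)
    assert depth == 1.0
    pts = RNG.uniform(-5000, 5000, (100, 3))
    coords, depths = assign_points(pts, pins)
    assert len(coords) == len(depths) == 100
    assert ((depths >= 0) & (depths <= 1)).all()


def test_assigned_depth_tracks_planted_depth(depth_table):
    err = np.abs(depth_table["depth"] - depth_table["true_depth"])
    assert err.mean() < 0.05


def test_pins_from_synthetic_volume_have_the_preset_count(built_pins):
    assert all(p.n_samp == 121 for p in built_pins.values())
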
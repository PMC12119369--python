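"""Layer boundaries: depth histograms, implicit peak thresholds, schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonnade.errors import InvalidDepthError, MarkerResolutionError
from colonnade.layers import (
    DepthDistribution,
    LayerScheme,
    MarkerSpec,
    assign_layer,
    assign_layers,
    build_layer_scheme,
    depth_distribution,
    find_peak_cutoffs,
    syn_threshold,
)


def test_histogram_conserves_counts_and_localizes():
    d = depth_distribution(np.full(50, 0.5), n_samp=121)
    assert d.bins.sum() == 50
    assert (d.bins > 0).sum() == 1
    assert np.argmax(d.bins) == 60  # station 0.5 * 120


def test_subsampling_halves_the_stations():
    depths = np.linspace(0, 1, 500)
    full = depth_distribution(depths, n_samp=121)
    sub = depth_distribution(depths, n_samp=121, subsample=True)
    assert len(full.bins) == 121 and len(sub.bins) == 61
    assert sub.bins.sum() == full.bins.sum() == 500


def test_empty_distribution_is_flagged():
    d = depth_distribution(np.array([]), n_samp=121)
    assert d.empty


def test_rectangular_peak_cutoffs():
    bins = np.zeros(40)
    bins[10:20] = 5.0  # peak over stations [10, 20)
    pairs = find_peak_cutoffs(bins, frac_peaks=0.85)
    assert pairs == [(10, 20)]


def test_close_peaks_merge_under_the_separation_rule():
    bins = np.zeros(40)
    bins[10:14] = 5.0
    bins[15:19] = 5.0  # gap of 1 station < 3
    pairs = find_peak_cutoffs(bins, frac_peaks=0.85)
    assert pairs == [(10, 19)]
    # well-separated peaks stay distinct
    bins = np.zeros(40)
    bins[10:14] = 5.0
    bins[20:24] = 5.0
    assert find_peak_cutoffs(bins, frac_peaks=0.85) == [(10, 14), (20, 24)]


def test_all_zero_distribution_has_no_peaks():
    assert find_peak_cutoffs(np.zeros(30), frac_peaks=0.8) == []


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    counts=st.lists(st.integers(0, 20), min_size=10, max_size=40),
    scale=st.sampled_from([2.0, 10.0, 0.5]),
)
def test_cutoffs_invariant_to_count_rescaling(counts, scale):
    bins = np.asarray(counts, dtype=float)
    assert find_peak_cutoffs(bins, 0.8) == find_peak_cutoffs(bins * scale, 0.8)
    assert syn_threshold(bins * scale, 0.8) == pytest.approx(
        scale * syn_threshold(bins, 0.8)
    )


def test_boundary_monotone_in_marker_peak_position():
    def boundary(shift):
        bins = np.zeros(61)
        bins[10 + shift: 20 + shift] = 5.0
        dist = DepthDistribution("M", "medulla", "pre", bins)
        scheme = build_layer_scheme(
            [MarkerSpec("M", "pre", 0, "upper")], {("M", "pre"): dist},
            "medulla", ["L1", "L2"], frac_peaks=0.85,
        )
        return scheme.boundaries[0]

    values = [boundary(s) for s in range(0, 20, 4)]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_single_marker_scheme_partitions_the_unit_interval():
    bins = np.zeros(61)
    bins[25:31] = 4.0
    dist = DepthDistribution("M", "medulla", "pre", bins)
    scheme = build_layer_scheme(
        [MarkerSpec("M", "pre", 0, "upper")], {("M", "pre"): dist},
        "medulla", ["shallow", "deep"], frac_peaks=0.85,
    )
    assert len(scheme.boundaries) == 1
    for d in np.linspace(0, 1, 101):
        assert assign_layer(d, scheme) in ("shallow", "deep")


def test_lobula_plate_boundary_is_the_mean_of_two_thresholds():
    # rectangular peaks whose upper cut-offs sit at stations 12 and 18 of 61
    def dist(hi):
        bins = np.zeros(61)
        bins[6:hi] = 5.0
        return DepthDistribution("T4", "lobula_plate", "pre", bins)

    dists = {("T4a", "pre"): dist(13), ("T4b", "pre"): dist(19)}
    scheme = build_layer_scheme(
        [(MarkerSpec("T4a", "pre", 0, "upper"), MarkerSpec("T4b", "pre", 0, "upper"))],
        dists, "lobula_plate", ["LOP1", "LOP2"], frac_peaks=0.75,
        lobula_plate_mode=True,
    )
    assert scheme.boundaries[0] == pytest.approx((13 / 60 + 19 / 60) / 2)


def test_unresolvable_marker_names_the_spec():
    dist = DepthDistribution("M", "medulla", "pre", np.zeros(61))
    with pytest.raises(MarkerResolutionError, match="M"):
        build_layer_scheme(
            [MarkerSpec("M", "pre", 0, "upper")], {("M", "pre"): dist},
            "medulla", ["a", "b"], frac_peaks=0.85,
        )


def test_layer_lookup_conventions():
    scheme = LayerScheme("medulla", np.array([0.3, 0.6]), ["A", "B", "C"])
    assert assign_layer(0.0, scheme) == "A"
    assert assign_layer(0.3, scheme) == "B"  # boundary -> deeper layer
    assert assign_layer(1.0, scheme) == "C"
    with pytest.raises(InvalidDepthError):
        assign_layer(1.5, scheme)
    with pytest.raises(InvalidDepthError):
        assign_layers(np.array([0.2, -0.1]), scheme)


def test_marker_boundaries_separate_planted_depth_peaks(volume, depth_table):
    """End-to-end: boundaries land between the planted per-type peaks."""
    merged = depth_table.merge(
        volume.neurons[["neuron_id", "true_type"]], on="neuron_id"
    )
    dists = {}
    for t in ("ColA", "ColB", "ColC"):
        sub = merged[(merged["true_type"] == t) & (merged["polarity"] == "pre")]
        dists[(t, "pre")] = depth_distribution(
            sub["depth"].to_numpy(), 121, cell_type=t, polarity="pre", subsample=True
        )
    scheme = build_layer_scheme(
        [MarkerSpec(t, "pre", 0, "upper") for t in ("ColA", "ColB", "ColC")],
        dists, "medulla", ["M1", "M2", "M3", "M4"],
    )
    b = scheme.boundaries
    # planted presynaptic peaks sit at depths 0.10, 0.40, 0.70, 0.90
    assert 0.10 < b[0] < 0.40 < b[1] < 0.70 < b[2] < 0.90


def test_single_layer_type_lands_in_its_layer(volume, depth_table):
    merged = depth_table.merge(
        volume.neurons[["neuron_id", "true_type"]], on="neuron_id"
    )
    # boundary far from ColB's planted support [0.32, 0.48]
    scheme = LayerScheme("medulla", np.array([0.25, 0.55]), ["M1", "M2", "M3"])
    colb = merged[(merged["true_type"] == "ColB") & (merged["polarity"] == "pre")]
    layers = assign_layers(colb["depth"].to_numpy(), scheme)
    assert (layers == "M2").mean() >= 0.95
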
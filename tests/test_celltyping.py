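"""Feature construction, clustering, confusion scoring, fingerprints."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from colonnade.celltyping import (
    build_conn_features,
    build_morph_features,
    cluster_features,
    confusion_summary,
    effective_partner_label,
    iterative_typing,
    mosaic_projection,
    top_n_fingerprint_uniqueness,
)
from colonnade.hexgrid import axial_to_xy


def _conn(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "weight", "region"])


def test_connectivity_feature_worked_example():
    # neuron 1: 3 inputs from two X cells, 2 outputs to one Y cell
    conn = _conn([
        (10, 1, 2, "ME_R"), (11, 1, 1, "ME_R"), (1, 20, 2, "ME_R"),
    ])
    labels = {10: "X", 11: "X", 20: "Y"}
    f = build_conn_features(conn, labels, neurons=[1])
    assert f.loc[1, ("X", "input")] == 3
    assert f.loc[1, ("Y", "output")] == 2
    assert f.loc[1].sum() == 5


def test_unclear_partners_excluded_fragments_folded_in():
    conn = _conn([
        (10, 1, 5, "ME_R"), (11, 1, 7, "ME_R"), (12, 1, 2, "ME_R"),
    ])
    labels = {10: "R7_unclear", 11: "X_fragment", 12: "X"}
    f = build_conn_features(conn, labels, neurons=[1])
    assert ("R7_unclear", "input") not in f.columns
    assert f.loc[1, ("X", "input")] == 9  # fragment counted under X
    assert effective_partner_label("Mi9", "Mi9_L") == "Mi9_L"
    assert effective_partner_label("Dm4_unclear") is None


def test_region_restriction_applies():
    conn = _conn([(10, 1, 5, "ME_R"), (10, 1, 5, "CB")])
    f = build_conn_features(conn, {10: "X"}, neurons=[1], regions={"ME_R"})
    assert f.loc[1, ("X", "input")] == 5


def test_disjoint_profiles_cluster_perfectly():
    rng = np.random.default_rng(0)
    a = np.column_stack([rng.poisson(10, 20), np.zeros(20)])
    b = np.column_stack([np.zeros(20), rng.poisson(10, 20)])
    X = pd.DataFrame(np.vstack([a, b]), index=range(40))
    labels = cluster_features(X, metric="cosine", n_clusters=2)
    truth = np.array([0] * 20 + [1] * 20)
    s = confusion_summary(pd.Series(truth, index=X.index), labels)
    assert s.completeness == 1.0 and s.homogeneity == 1.0


def test_duplicated_rows_co_cluster_and_singletons_at_max_k():
    X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 0.1], [0.1, 7.0]])
    labels = cluster_features(X, metric="euclidean", n_clusters=3)
    assert labels.iloc[0] == labels.iloc[1]
    labels = cluster_features(X, metric="euclidean", n_clusters=4)
    assert labels.nunique() == 4


def test_zero_vectors_excluded_under_cosine():
    X = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    with pytest.warns(UserWarning, match="zero vector"):
        labels = cluster_features(X, metric="cosine", n_clusters=2)
    assert 2 not in labels.index


def test_cosine_and_l2_euclidean_routes_co_cluster():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(np.vstack([
        rng.poisson([20, 1, 1], (15, 3)), rng.poisson([1, 20, 1], (15, 3)),
    ]) + 0.0)
    a = cluster_features(X, metric="cosine", n_clusters=2)
    b = cluster_features(X, metric="l2euclidean", n_clusters=2)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(a, b) == 1.0


# ----------------------------------------------------------- morphology

def _syn(rows):
    return pd.DataFrame(rows, columns=["polarity", "confidence", "p", "q", "depth"])


def test_morphology_vector_shape_and_single_entry_blocks():
    syn = _syn([("pre", 0.95, 0, 0, 0.5)])
    v = build_morph_features(syn)
    assert len(v) == 244
    # one presynapse at one depth in one column: block 1 has a single entry
    # equal to the innervated-column count (1), block 3 a single 1
    assert (v[:61] > 0).sum() == 1 and v[:61].sum() == pytest.approx(1.0)
    assert (v[122:183] > 0).sum() == 1 and v[122:183].sum() == 1.0
    assert np.all(v[61:122] == 0) and np.all(v[183:] == 0)


def test_morphology_normalization_is_count_invariant():
    syn = _syn([
        ("pre", 0.95, 0, 0, 0.1), ("pre", 0.95, 1, 0, 0.1), ("pre", 0.95, 0, 0, 0.8),
        ("post", 0.95, 0, 0, 0.4),
    ])
    v1 = build_morph_features(syn)
    v10 = build_morph_features(pd.concat([syn] * 10, ignore_index=True))
    # duplicating every synapse leaves normalized blocks and column blocks alone
    assert np.allclose(v1[:122], v10[:122])
    assert np.allclose(v1[122:], v10[122:])


def test_low_confidence_synapses_ignored():
    syn = _syn([("pre", 0.5, 0, 0, 0.5), ("pre", 0.95, 0, 0, 0.2)])
    v = build_morph_features(syn)
    assert v[122:183].sum() == 1.0  # only the confident synapse counts


def test_block1_sum_equals_presynaptic_column_count(depth_table):
    some = depth_table[depth_table["neuron_id"] == depth_table["neuron_id"].iloc[0]]
    v = build_morph_features(some)
    pre = some[(some["polarity"] == "pre") & (some["confidence"] >= 0.9)]
    sub = (np.rint(pre["depth"] * 120).astype(int) // 2)
    n_size = sum(
        len(g[["p", "q"]].drop_duplicates()) for _, g in pre.groupby(sub)
    )
    assert v[:61].sum() == pytest.approx(n_size)
    assert v[122:183].sum() == n_size


# ------------------------------------------------------------ confusion

def test_identical_labelings_are_all_red():
    truth = pd.Series(["a"] * 5 + ["b"] * 5)
    s = confusion_summary(truth, truth.map({"a": 1, "b": 2}))
    nonzero = s.matrix.to_numpy() > 0
    assert (s.categories.to_numpy()[nonzero] == "red").all()
    assert s.completeness == s.homogeneity == 1.0


def test_split_type_is_green_merged_types_are_blue():
    truth = pd.Series(["a"] * 10)
    split = pd.Series([1] * 5 + [2] * 5)
    s = confusion_summary(truth, split)
    assert set(s.categories.to_numpy()[s.matrix.to_numpy() > 0]) == {"green"}
    assert s.homogeneity == 1.0 and s.completeness < 1.0

    truth = pd.Series(["a"] * 5 + ["b"] * 5)
    merged = pd.Series([1] * 10)
    s = confusion_summary(truth, merged)
    assert set(s.categories.to_numpy()[s.matrix.to_numpy() > 0]) == {"blue"}
    assert s.completeness == 1.0 and s.homogeneity < 1.0


def test_categories_are_exhaustive_on_random_labelings():
    rng = np.random.default_rng(17)
    for _ in range(20):
        truth = pd.Series(rng.integers(0, 4, 60).astype(str))
        pred = pd.Series(rng.integers(0, 5, 60))
        s = confusion_summary(truth, pred)
        nonzero = s.matrix.to_numpy() > 0
        cats = s.categories.to_numpy()
        assert set(cats[nonzero]) <= {"red", "blue", "green", "yellow", "grey"}
        assert (cats[nonzero] != "").all()
        assert (cats[~nonzero] == "").all()
        assert (s.matrix.sum(axis=1).to_numpy() == truth.value_counts().sort_index().to_numpy()).all()


# ---------------------------------------------------------- fingerprints

def _type_table(rows):
    return pd.DataFrame(rows, columns=["type", "partner", "direction", "weight"])


def test_disjoint_partner_sets_are_fully_unique():
    t = _type_table([
        ("a", "x", "output", 5), ("b", "y", "output", 5), ("c", "z", "output", 5),
    ])
    assert top_n_fingerprint_uniqueness(t, 1) == 1.0


def test_identical_types_are_both_non_unique():
    t = _type_table([
        ("a", "x", "output", 5), ("b", "x", "output", 7),
        ("c", "y", "output", 5), ("d", "z", "output", 5),
    ])
    # a and b share the same top-1 set {x/output}
    assert top_n_fingerprint_uniqueness(t, 1) == pytest.approx(2 / 4)


def test_uniqueness_is_monotone_in_n():
    rng = np.random.default_rng(23)
    partners = [f"p{i}" for i in range(6)]
    rows = []
    for t in range(8):
        for p in partners:
            rows.append((f"t{t}", p, "output", int(rng.integers(1, 50))))
    table = _type_table(rows)
    values = [top_n_fingerprint_uniqueness(table, n) for n in range(1, 7)]
    assert all(b >= a for a, b in zip(values, values[1:]))


# --------------------------------------------------------------- mosaics

def test_mosaic_projection_preserves_lattice_geometry():
    # retinotopic extent must dominate depth for the reference PCA to pick
    # the lateral plane, as in a real neuropil shell
    from colonnade.synthetic import default_specs, generate_volume

    vol = generate_volume(default_specs(37), seed=31, n_rings=3, depth=10_000.0)
    syn = vol.synapses.merge(
        vol.neurons[["neuron_id", "true_type", "home_p", "home_q"]], on="neuron_id"
    )
    cola = syn[syn["true_type"] == "ColA"]
    reference = syn[syn["true_type"] != "Ov5"][["x", "y", "z"]].to_numpy()
    proj = mosaic_projection(cola, reference)
    homes = cola.groupby("neuron_id")[["home_p", "home_q"]].first()
    true_xy = axial_to_xy(homes["home_p"], homes["home_q"], vol.grid.spacing)
    n = len(proj)
    d2 = np.linalg.norm(proj.to_numpy()[:, None] - proj.to_numpy()[None], axis=-1)
    dt = np.linalg.norm(true_xy[:, None] - true_xy[None], axis=-1)
    iu = np.triu_indices(n, 1)
    rho, _ = spearmanr(d2[iu], dt[iu])
    assert rho > 0.9


def test_projection_invariant_to_duplicating_synapses(volume):
    syn = volume.synapses[volume.synapses["neuron_id"] <= 5]
    ref = syn[["x", "y", "z"]].to_numpy()
    a = mosaic_projection(syn, ref)
    b = mosaic_projection(pd.concat([syn] * 2, ignore_index=True), ref)
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_single_cell_sits_at_the_origin_of_its_own_frame():
    rng = np.random.default_rng(2)
    syn = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x", "y", "z"])
    syn["neuron_id"] = 1
    proj = mosaic_projection(syn, syn[["x", "y", "z"]].to_numpy())
    assert np.allclose(proj.loc[1].to_numpy(), 0.0, atol=1e-9)


# ------------------------------------------------------ iterative typing

def test_iterative_typing_converges_on_separable_volume(volume):
    labels = volume.neurons.set_index("neuron_id")["true_type"]
    refined, rounds = iterative_typing(volume.connections, labels, n_clusters=5)
    assert rounds <= 3
    assert (refined == labels).all()
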
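"""Connectivity and morphology feature vectors, clustering, and scoring.

Cells are grouped into types by the aggregate of their connections to
already-named types (inputs and outputs kept separate), or by a 244-long
morphology profile of synapse counts and column innervation across medulla
depth.  Hierarchical clustering (Ward linkage; cosine distance for
connectivity, Euclidean for morphology) is cut into a preselected number of
flat clusters, and cluster-type agreement is summarized in a confusion
matrix with five mutually exclusive cell categories plus completeness and
homogeneity scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import completeness_score, homogeneity_score

from .errors import InvalidParameterError

__all__ = [
    "effective_partner_label",
    "build_conn_features",
    "cluster_features",
    "build_morph_features",
    "build_morph_feature_table",
    "ConfusionSummary",
    "confusion_summary",
    "top_n_fingerprint_uniqueness",
    "mosaic_projection",
    "iterative_typing",
]


def effective_partner_label(cell_type: str, instance: str | None = None) -> str | None:
    """Partner label used in connectivity features, or None to exclude.

    Partners typed ``*_unclear`` are excluded; ``*_fragment`` bodies count
    under their parent type; bilateral partners (instances ending in _L/_R)
    are split by side, because left- and right-instance connectivity in one
    optic lobe can differ substantially.
    """
    if "_unclear" in cell_type:
        return None
    label = cell_type
    if label.endswith("_fragment"):
        label = label[: -len("_fragment")]
    if instance and instance.rsplit("_", 1)[-1] in ("L", "R"):
        side = instance.rsplit("_", 1)[-1]
        label = f"{label}_{side}"
    return label


def build_conn_features(
    connections: pd.DataFrame,
    labels: Mapping | pd.Series,
    neurons: Sequence | None = None,
    instances: Mapping | pd.Series | None = None,
    regions: set | None = None,
) -> pd.DataFrame:
    """Per-neuron connectivity feature table.

    Each featurized neuron gets the sum of its connection weights to every
    named partner type, split into input and output directions and
    restricted to ``regions`` when given.  ``labels`` maps partner neuron
    ids to type names (partial coverage is fine: connections to unlabelled
    partners are ignored); ``neurons`` selects the rows (default: all ids
    appearing in the connection table).  Neurons ending up with an all-zero
    row are kept but reported with a warning.
    """
    conn = connections
    if regions is not None:
        conn = conn[conn["region"].isin(regions)]
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    instances = pd.Series(instances) if isinstance(instances, Mapping) else instances

    def partner_label(nid):
        t = labels.get(nid)
        if t is None or (isinstance(t, float) and np.isnan(t)):
            return None
        inst = instances.get(nid) if instances is not None else None
        return effective_partner_label(str(t), inst)

    if neurons is None:
        neurons = sorted(set(conn["pre_id"]).union(conn["post_id"]))
    index = pd.Index(neurons, name="neuron_id")
    sums: dict[tuple[str, str], pd.Series] = {}
    for direction, own_col, partner_col in (
        ("output", "pre_id", "post_id"),
        ("input", "post_id", "pre_id"),
    ):
        sub = conn[conn[own_col].isin(index)]
        plabels = sub[partner_col].map(partner_label)
        sub = sub.assign(_label=plabels).dropna(subset=["_label"])
        grouped = sub.groupby([own_col, "_label"])["weight"].sum()
        for (nid, lab), w in grouped.items():
            sums.setdefault((lab, direction), pd.Series(0.0, index=index))[nid] = w
    if sums:
        features = pd.DataFrame(sums).fillna(0.0)
        features.columns = pd.MultiIndex.from_tuples(features.columns, names=["partner", "direction"])
        features = features.sort_index(axis=1)
    else:
        features = pd.DataFrame(index=index)
    zero = features.index[features.sum(axis=1) == 0] if len(features.columns) else features.index
    if len(zero):
        warnings.warn(f"{len(zero)} neuron(s) have zero in-scope connections", stacklevel=2)
    return features


def cluster_features(
    features: pd.DataFrame,
    metric: str = "cosine",
    n_clusters: int = 2,
) -> pd.Series:
    """Ward-linkage agglomerative clustering cut into flat clusters.

    ``metric`` is ``cosine`` (connectivity), ``euclidean`` (morphology) or
    ``l2euclidean`` (L2-normalize rows, then Euclidean — the alternative
    normalization route, which co-clusters with cosine on well-separated
    data).  Zero rows are excluded under cosine (distance undefined) with a
    warning.  Returns cluster labels (1..n_clusters) indexed by neuron id.
    """
    X = features.to_numpy(dtype=float)
    index = features.index
    if metric in ("cosine", "l2euclidean"):
        norms = np.linalg.norm(X, axis=1)
        keep = norms > 0
        if not keep.all():
            warnings.warn(
                f"excluding {int((~keep).sum())} zero vector(s): cosine distance undefined",
                stacklevel=2,
            )
            X, index = X[keep], index[keep]
    if n_clusters > len(X):
        raise InvalidParameterError("n_clusters exceeds the number of neurons")
    if metric == "cosine":
        d = pdist(X, metric="cosine")
    elif metric == "l2euclidean":
        d = pdist(X / np.linalg.norm(X, axis=1, keepdims=True), metric="euclidean")
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    Z = linkage(d, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=index, name="cluster")


def build_morph_features(
    synapses: pd.DataFrame,
    n_samp: int = 121,
    confidence_min: float = 0.9,
) -> np.ndarray:
    """244-long medulla morphology vector for one neuron.

    Four blocks of 61 depth stations (121 pin stations subsampled by 2):
    presynapse counts normalized so the block sums to the presynaptic
    innervated-column count, the same for postsynapses, then the raw
    per-depth presynaptic and postsynaptic innervated-column counts.
    ``synapses`` needs columns polarity, confidence, p, q and depth (or
    station).  Only synapses at or above ``confidence_min`` contribute.
    """
    n_sub = (n_samp + 1) // 2
    syn = synapses[synapses["confidence"] >= confidence_min]
    if "station" in syn.columns:
        station = syn["station"].to_numpy(dtype=int)
    else:
        station = np.rint(syn["depth"].to_numpy(dtype=float) * (n_samp - 1)).astype(int)
    sub = station // 2
    blocks = []
    col_blocks = []
    for polarity in ("pre", "post"):
        mask = (syn["polarity"] == polarity).to_numpy()
        counts = np.bincount(sub[mask], minlength=n_sub).astype(float)
        cols = np.zeros(n_sub)
        if mask.any():
            per = pd.DataFrame(
                {"d": sub[mask], "p": syn["p"].to_numpy()[mask], "q": syn["q"].to_numpy()[mask]}
            )
            ncols = per.groupby("d").apply(
                lambda g: len(g[["p", "q"]].drop_duplicates()), include_groups=False
            )
            cols[ncols.index.to_numpy()] = ncols.to_numpy()
        n_syn, n_size = counts.sum(), cols.sum()
        normed = counts * (n_size / n_syn) if n_syn > 0 else counts
        blocks.append(normed)
        col_blocks.append(cols)
    return np.concatenate([blocks[0], blocks[1], col_blocks[0], col_blocks[1]])


def build_morph_feature_table(
    synapses: pd.DataFrame, n_samp: int = 121, confidence_min: float = 0.9
) -> pd.DataFrame:
    """Morphology feature vectors for every neuron in a synapse table."""
    rows = {
        nid: build_morph_features(grp, n_samp=n_samp, confidence_min=confidence_min)
        for nid, grp in synapses.groupby("neuron_id", sort=True)
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "neuron_id"
    return out


@dataclass
class ConfusionSummary:
    """Type-by-cluster neuron counts with per-cell categories and scores.

    Categories (mutually exclusive, exhaustive over nonzero cells):
    ``red`` 1-to-1, ``blue`` many-to-1, ``green`` 1-to-many, ``yellow``
    mixed, ``grey`` outlier, per the 80% / 10% fraction rules.
    """

    matrix: pd.DataFrame
    categories: pd.DataFrame
    completeness: float
    homogeneity: float


def confusion_summary(true_types, cluster_labels) -> ConfusionSummary:
    """Score a clustering against reference type labels.

    Rows (types) are ordered lexicographically; columns (clusters) follow
    the greedy procedure: walk the types in order, picking each type's
    clusters by descending neuron count until the remaining clusters hold
    5% or less of that type, then move on; leftover clusters append at the
    end.
    """
    true = pd.Series(true_types)
    pred = pd.Series(cluster_labels)
    pred = pred.reindex(true.index)
    M = pd.crosstab(true, pred)
    M = M.sort_index(axis=0)

    ordered: list = []
    remaining = set(M.columns)
    for t in M.index:
        row = M.loc[t]
        size = row.sum()
        for c in row.sort_values(ascending=False, kind="stable").index:
            if c not in remaining:
                continue
            if row[c] <= 0.05 * size:
                break
            ordered.append(c)
            remaining.discard(c)
    ordered.extend(sorted(remaining))
    M = M[ordered]

    row_sum = M.sum(axis=1)
    col_sum = M.sum(axis=0)
    cats = pd.DataFrame("", index=M.index, columns=M.columns, dtype=object)
    for t in M.index:
        for c in M.columns:
            n = M.loc[t, c]
            if n == 0:
                continue
            ft = n / row_sum[t]
            fc = n / col_sum[c]
            if ft >= 0.8:
                cats.loc[t, c] = "red" if fc >= 0.8 else "blue"
            elif ft >= 0.1:
                cats.loc[t, c] = "green" if fc >= 0.8 else ("yellow" if fc >= 0.1 else "grey")
            else:
                cats.loc[t, c] = "grey"
    return ConfusionSummary(
        matrix=M,
        categories=cats,
        completeness=float(completeness_score(true, pred)),
        homogeneity=float(homogeneity_score(true, pred)),
    )


def top_n_fingerprint_uniqueness(type_connectivity: pd.DataFrame, n: int) -> float:
    """Proportion of types whose top-n connection fingerprint is unique.

    ``type_connectivity`` has columns type, partner, direction, weight
    (type-level aggregated connections).  For each type the ``n`` strongest
    (partner, direction) pairs are taken in rank order (ties broken by
    partner name then direction); a type is unique when no other type has
    the same ranked fingerprint.  Keeping the rank order gives the
    fingerprints the prefix property, so the uniqueness proportion is
    non-decreasing in n.
    """
    fingerprints: dict[str, tuple] = {}
    for t, grp in type_connectivity.groupby("type"):
        ranked = grp.sort_values(
            ["weight", "partner", "direction"], ascending=[False, True, True], kind="stable"
        )
        top = ranked.head(n)
        fingerprints[t] = tuple(zip(top["partner"], top["direction"]))
    counts: dict[tuple, int] = {}
    for fp in fingerprints.values():
        counts[fp] = counts.get(fp, 0) + 1
    unique = sum(1 for fp in fingerprints.values() if counts[fp] == 1)
    return unique / len(fingerprints) if fingerprints else float("nan")


def mosaic_projection(
    cell_synapses: pd.DataFrame, reference_xyz: np.ndarray
) -> pd.DataFrame:
    """2D mosaic view: cells at their synapse centre-of-mass, projected onto
    the first two principal axes of a fixed reference synapse set.

    Using one reference PCA per neuropil standardizes the view across cell
    types.  Cells with no synapses are simply absent from the input and
    therefore excluded.  Returns a frame indexed by neuron id with columns
    pc1, pc2.
    """
    ref = np.asarray(reference_xyz, dtype=float)
    pca = PCA(n_components=2).fit(ref)
    coms = cell_synapses.groupby("neuron_id")[["x", "y", "z"]].mean()
    proj = pca.transform(coms.to_numpy())
    return pd.DataFrame(proj, index=coms.index, columns=["pc1", "pc2"])


def iterative_typing(
    connections: pd.DataFrame,
    initial_labels: pd.Series,
    n_clusters: int,
    max_rounds: int = 5,
    metric: str = "cosine",
) -> tuple[pd.Series, int]:
    """Preliminary-labels -> cluster -> refined-labels loop.

    Each round rebuilds connectivity features against the current labels,
    reclusters, and relabels every neuron with the majority label of its
    cluster.  Stops when the labelling is stable or after ``max_rounds``.
    Returns (labels, rounds used).
    """
    labels = pd.Series(initial_labels).copy()
    for round_no in range(1, max_rounds + 1):
        features = build_conn_features(connections, labels, neurons=labels.index)
        clusters = cluster_features(features, metric=metric, n_clusters=n_clusters)
        new_labels = labels.copy()
        for c, members in clusters.groupby(clusters):
            majority = labels.loc[members.index].mode().iloc[0]
            new_labels.loc[members.index] = majority
        if new_labels.equals(labels):
            return labels, round_no
        labels = new_labels
    return labels, max_rounds
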
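"""Staged analysis pipeline over a (synthetic) connectome export.

Stages run in the order the method requires: simulate -> coordinates ->
pins -> layers -> typecells -> match -> coverage -> nt -> projectome.
Each stage reads its inputs from the run directory, writes its outputs
there, and records itself in ``manifest.json``; a failed stage halts the
run with its name while earlier outputs are preserved.  All randomness
flows from the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import celltyping, coverage as cov, hexgrid, interregion, layers as lay
from . import matching as mat, neurotransmitters as nt, pins as pinmod, synthetic
from .io import PipelineConfig, read_tables

__all__ = ["STAGES", "run_pipeline", "run_stage"]

log = logging.getLogger("colonnade")


def _manifest_update(out: Path, stage: str, files: list[str], params: dict) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
    manifest["stages"][stage] = {"files": files, "params": params}
    mpath.write_text(json.dumps(manifest, indent=2, default=str))


def _load_volume_tables(cfg: PipelineConfig, out: Path):
    return read_tables(
        out / "neurons.csv", out / "synapses.csv", out / "connections.csv",
        confidence_min=cfg.confidence_min,
    )


def _load_grid_axes(out: Path):
    grid = pd.read_csv(out / "grid.csv")
    axes = []
    for (p, q), grp in grid.groupby(["p", "q"], sort=True):
        pts = grp.sort_values("point_index")[["x", "y", "z"]].to_numpy(dtype=float)
        axes.append(SimpleNamespace(coordinate=hexgrid.HexCoordinate(int(p), int(q)), points=pts))
    return axes


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    n_columns = 1 + 3 * cfg.n_rings * (cfg.n_rings + 1)
    vol = synthetic.generate_volume(
        synthetic.default_specs(n_columns),
        seed=cfg.seed,
        n_rings=cfg.n_rings,
        spacing=cfg.spacing_nm,
        curvature=cfg.curvature,
        depth=cfg.depth_nm,
        jitter_sigma=cfg.jitter_sigma_nm,
    )
    synthetic.write_volume(vol, out)
    log.info("simulate: %d neurons, %d synapses, %d connections (seed=%d)",
             len(vol.neurons), len(vol.synapses), len(vol.connections), cfg.seed)
    _manifest_update(out, "simulate",
                     ["neurons.csv", "synapses.csv", "connections.csv", "grid.csv"],
                     {"seed": cfg.seed, "n_rings": cfg.n_rings, "spacing_nm": cfg.spacing_nm})


def stage_coordinates(cfg: PipelineConfig, out: Path) -> None:
    _, synapses, _ = _load_volume_tables(cfg, out)
    seed_axes = _load_grid_axes(out)
    assignment, _ = hexgrid.bootstrap_assignments(
        synapses, seed_axes, n_iter=cfg.coord_iterations
    )
    assignment.reset_index().to_csv(out / "coordinates.csv", index=False)
    log.info("coordinates: %d neurons assigned (%d ambiguous, %d iterations)",
             len(assignment), int(assignment["ambiguous"].sum()), cfg.coord_iterations)
    _manifest_update(out, "coordinates", ["coordinates.csv"],
                     {"iterations": cfg.coord_iterations})


def stage_pins(cfg: PipelineConfig, out: Path) -> None:
    _, synapses, _ = _load_volume_tables(cfg, out)
    coords = pd.read_csv(out / "coordinates.csv")
    merged = synapses.merge(coords[["neuron_id", "p", "q"]], on="neuron_id")
    neuropil = pinmod.Neuropil.slab("medulla", 0.0, cfg.depth_nm)
    params = pinmod.PinParams(
        f_lat=cfg.f_lat, n_pc=cfg.n_pc, n_avg=cfg.n_avg,
        n_tang=cfg.n_tang, n_samp=cfg.n_samp, name="medulla",
    )
    built, rejected = pinmod.build_pins(merged, neuropil, params)
    grid_coords = [ax.coordinate for ax in _load_grid_axes(out)]
    pins = pinmod.regularize_and_fill(built, coords=grid_coords)
    rows = []
    for c in sorted(pins):
        for i, pt in enumerate(pins[c].points):
            rows.append({"p": c.p, "q": c.q, "point_index": i,
                         "x": pt[0], "y": pt[1], "z": pt[2],
                         "provenance": pins[c].provenance})
    pd.DataFrame(rows).to_csv(out / "pins.csv", index=False)
    syn_coords, depths = pinmod.assign_points(
        synapses[["x", "y", "z"]].to_numpy(dtype=float), pins
    )
    depth_table = synapses[["neuron_id", "polarity", "confidence"]].copy()
    depth_table["p"] = [c.p for c in syn_coords]
    depth_table["q"] = [c.q for c in syn_coords]
    depth_table["depth"] = depths
    depth_table.to_csv(out / "depths.csv", index=False)
    log.info("pins: %d built, %d rejected, %d after fill-in (n_samp=%d)",
             len(built), len(rejected), len(pins), cfg.n_samp)
    _manifest_update(out, "pins", ["pins.csv", "depths.csv"],
                     {"f_lat": cfg.f_lat, "n_pc": cfg.n_pc, "n_avg": cfg.n_avg,
                      "n_tang": cfg.n_tang, "n_samp": cfg.n_samp})


#: default layer markers for the synthetic medulla: the upper cut-off of the
#: single presynaptic peak of three columnar marker types
DEFAULT_MARKERS = [
    lay.MarkerSpec("ColA", "pre", 0, "upper"),
    lay.MarkerSpec("ColB", "pre", 0, "upper"),
    lay.MarkerSpec("ColC", "pre", 0, "upper"),
]
DEFAULT_LAYER_NAMES = ["M1", "M2", "M3", "M4"]


def stage_layers(cfg: PipelineConfig, out: Path) -> None:
    neurons, _, _ = _load_volume_tables(cfg, out)
    depths = pd.read_csv(out / "depths.csv")
    merged = depths.merge(neurons[["neuron_id", "type"]], on="neuron_id")
    dists = {}
    for spec in DEFAULT_MARKERS:
        sub = merged[(merged["type"] == spec.cell_type) & (merged["polarity"] == spec.polarity)]
        dists[(spec.cell_type, spec.polarity)] = lay.depth_distribution(
            sub["depth"].to_numpy(), cfg.n_samp, cell_type=spec.cell_type,
            polarity=spec.polarity, subsample=True,
        )
    scheme = lay.build_layer_scheme(
        DEFAULT_MARKERS, dists, "medulla", DEFAULT_LAYER_NAMES, frac_peaks=cfg.frac_peaks
    )
    depths["layer"] = lay.assign_layers(depths["depth"].to_numpy(), scheme)
    depths.to_csv(out / "depths.csv", index=False)
    with open(out / "layers.json", "w") as fh:
        json.dump({"neuropil": scheme.neuropil,
                   "boundaries": scheme.boundaries.tolist(),
                   "names": scheme.names}, fh, indent=2)
    log.info("layers: boundaries %s (frac_peaks=%.2f)",
             np.round(scheme.boundaries, 3).tolist(), cfg.frac_peaks)
    _manifest_update(out, "layers", ["layers.json", "depths.csv"],
                     {"frac_peaks": cfg.frac_peaks})


def stage_typecells(cfg: PipelineConfig, out: Path) -> None:
    neurons, synapses, connections = _load_volume_tables(cfg, out)
    labels = neurons.set_index("neuron_id")["type"]
    features = celltyping.build_conn_features(
        connections, labels, neurons=labels.index.tolist()
    )
    clusters = celltyping.cluster_features(
        features, metric=cfg.cluster_metric, n_clusters=cfg.n_clusters
    )
    summary = celltyping.confusion_summary(labels.loc[clusters.index], clusters)
    clusters.reset_index().to_csv(out / "clusters.csv", index=False)
    summary.matrix.to_csv(out / "confusion.csv")
    depths = pd.read_csv(out / "depths.csv")
    morph_in = depths.assign(confidence=synapses["confidence"].to_numpy())
    morph = celltyping.build_morph_feature_table(
        morph_in, n_samp=cfg.n_samp, confidence_min=cfg.morph_confidence_min
    )
    morph.to_csv(out / "morph_features.csv")
    log.info("typecells: k=%d, completeness=%.3f homogeneity=%.3f",
             cfg.n_clusters, summary.completeness, summary.homogeneity)
    _manifest_update(out, "typecells",
                     ["clusters.csv", "confusion.csv", "morph_features.csv"],
                     {"n_clusters": cfg.n_clusters, "metric": cfg.cluster_metric,
                      "completeness": summary.completeness,
                      "homogeneity": summary.homogeneity})


def stage_match(cfg: PipelineConfig, out: Path,
                anchor_type: str = "ColA", candidate_type: str = "ColB") -> None:
    neurons, synapses, connections = _load_volume_tables(cfg, out)
    types = neurons.set_index("neuron_id")["type"]
    anchors = sorted(types.index[types == anchor_type])
    candidates = sorted(types.index[types == candidate_type])
    C = np.zeros((len(anchors), len(candidates)))
    a_idx = {a: i for i, a in enumerate(anchors)}
    c_idx = {c: j for j, c in enumerate(candidates)}
    for r in connections.itertuples():
        if r.pre_id in a_idx and r.post_id in c_idx:
            C[a_idx[r.pre_id], c_idx[r.post_id]] += r.weight
    pairs = mat.max_weight_assignment(mat.normalize_rows(C))
    pre_pos = synapses[synapses["polarity"] == "pre"].groupby("neuron_id")[["x", "y", "z"]].mean()
    post_pos = synapses[synapses["polarity"] == "post"].groupby("neuron_id")[["x", "y", "z"]].mean()
    anchor_positions = {i: pre_pos.loc[a].to_numpy() for a, i in a_idx.items() if a in pre_pos.index}
    cand_positions = {j: post_pos.loc[c].to_numpy() for c, j in c_idx.items() if c in post_pos.index}
    accepted, rejected = mat.veto_by_distance(
        pairs, anchor_positions, cand_positions,
        threshold=cfg.distance_threshold_um * 1_000.0,
    )
    rows = [{"anchor": anchors[a], "candidate": candidates[c], "distance_nm": d,
             "accepted": True} for a, c, d in accepted]
    rows += [{"anchor": anchors[a], "candidate": candidates[c], "distance_nm": np.nan,
              "accepted": False, "reason": why} for a, c, why in rejected]
    pd.DataFrame(rows).to_csv(out / "matching.csv", index=False)
    log.info("match: %s->%s, %d accepted / %d rejected (threshold %.1f um)",
             anchor_type, candidate_type, len(accepted), len(rejected),
             cfg.distance_threshold_um)
    _manifest_update(out, "match", ["matching.csv"],
                     {"anchor": anchor_type, "candidate": candidate_type,
                      "distance_threshold_um": cfg.distance_threshold_um})


def stage_coverage(cfg: PipelineConfig, out: Path) -> None:
    neurons, _, _ = _load_volume_tables(cfg, out)
    depths = pd.read_csv(out / "depths.csv")
    merged = depths.merge(neurons[["neuron_id", "type"]], on="neuron_id")
    total_columns = len(pd.read_csv(out / "grid.csv")[["p", "q"]].drop_duplicates())
    rows = []
    for t, grp in merged.groupby("type", sort=True):
        counts = cov.column_counts(grp)
        s = cov.coverage_summary(counts, total_columns, type_name=t, neuropil="medulla")
        rows.append(asdict(s))
    pd.DataFrame(rows).to_csv(out / "coverage.csv", index=False)
    log.info("coverage: %d types summarized over %d columns", len(rows), total_columns)
    _manifest_update(out, "coverage", ["coverage.csv"], {"total_columns": total_columns})


def stage_nt(cfg: PipelineConfig, out: Path) -> None:
    neurons, synapses, connections = _load_volume_tables(cfg, out)
    prob_cols = [f"nt_{t}" for t in nt.TRANSMITTERS]
    pre = synapses[synapses["polarity"] == "pre"].copy()
    pre = pre.rename(columns=dict(zip(prob_cols, nt.TRANSMITTERS)))
    cell_rows = []
    for nid, grp in pre.groupby("neuron_id", sort=True):
        call = nt.cell_call(grp, min_presynapses=cfg.nt_cell_min_presynapses,
                            min_confidence=cfg.nt_min_confidence)
        cell_rows.append({"neuron_id": nid, **call._asdict()})
    pd.DataFrame(cell_rows).to_csv(out / "nt_cells.csv", index=False)

    types = neurons.set_index("neuron_id")["type"]
    out_counts = connections.groupby("pre_id")["weight"].sum()
    pre_counts = pre.groupby("neuron_id").size()
    type_rows = []
    for t, members in types.groupby(types):
        pooled = pre[pre["neuron_id"].isin(members.index)]
        call = nt.type_call(pooled, min_presynapses=cfg.nt_type_min_presynapses,
                            min_confidence=cfg.nt_min_confidence)
        consensus = nt.consensus_call(call, experimental_support=None)
        ids = members.index
        fo = nt.fanout(out_counts.reindex(ids, fill_value=0.0).to_numpy(),
                       pre_counts.reindex(ids, fill_value=0.0).to_numpy())
        type_rows.append({"type": t, **call._asdict(), "consensus": consensus, "fanout": fo})
    pd.DataFrame(type_rows).to_csv(out / "nt_types.csv", index=False)
    log.info("nt: %d cells, %d types called (cell>=%d, type>=%d presynapses)",
             len(cell_rows), len(type_rows),
             cfg.nt_cell_min_presynapses, cfg.nt_type_min_presynapses)
    _manifest_update(out, "nt", ["nt_cells.csv", "nt_types.csv"],
                     {"cell_min": cfg.nt_cell_min_presynapses,
                      "type_min": cfg.nt_type_min_presynapses,
                      "min_confidence": cfg.nt_min_confidence})


def stage_projectome(cfg: PipelineConfig, out: Path) -> None:
    depths = pd.read_csv(out / "depths.csv")
    if "layer" not in depths.columns:
        raise RuntimeError("projectome requires the layers stage output")
    neuron_io = []
    for _, grp in depths.groupby("neuron_id", sort=True):
        ins = grp[grp["polarity"] == "post"].groupby("layer").size().to_dict()
        outs = grp[grp["polarity"] == "pre"].groupby("layer").size().to_dict()
        neuron_io.append((ins, outs))
    region_order = DEFAULT_LAYER_NAMES
    rm = interregion.aggregate_group(neuron_io, regions=region_order, group="all")
    binned, mask = interregion.rank_and_bin(rm.matrix, cumulative_cut=cfg.cumulative_cut)
    rm.matrix.to_csv(out / "projectome.csv")
    binned.to_csv(out / "projectome_bins.csv")
    log.info("projectome: %d regions, %d connections shown at cut %.4f",
             len(rm.regions), int(mask.to_numpy().sum()), cfg.cumulative_cut)
    _manifest_update(out, "projectome", ["projectome.csv", "projectome_bins.csv"],
                     {"cumulative_cut": cfg.cumulative_cut})


STAGES = {
    "simulate": stage_simulate,
    "coordinates": stage_coordinates,
    "pins": stage_pins,
    "layers": stage_layers,
    "typecells": stage_typecells,
    "match": stage_match,
    "coverage": stage_coverage,
    "nt": stage_nt,
    "projectome": stage_projectome,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        STAGES[name](cfg, out)
    except Exception:
        log.exception("stage %r failed", name)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run all stages in order; returns the results directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for name in STAGES:
        run_stage(name, cfg, out)
    return out
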
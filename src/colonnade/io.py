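"""Readers/writers for the tabular connectome exports, SWC skeletons and
pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, SWCFormatError

__all__ = [
    "SCHEMAS",
    "DEFAULT_CONFIDENCE_MIN",
    "read_tables",
    "write_tables",
    "Skeleton",
    "read_swc",
    "write_swc",
    "PipelineConfig",
]

#: required columns per table (extra columns pass through untouched)
SCHEMAS = {
    "neurons": ["neuron_id", "type", "instance", "soma_x", "soma_y", "soma_z"],
    "synapses": ["neuron_id", "polarity", "x", "y", "z", "confidence"],
    "connections": ["pre_id", "post_id", "weight", "region"],
}

#: synapse detection-confidence filter applied on load
DEFAULT_CONFIDENCE_MIN = 0.5


def _validate(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} in {kind} table")
    return df


def read_tables(
    neurons_path,
    synapses_path,
    connections_path,
    confidence_min: float = DEFAULT_CONFIDENCE_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the neuron, synapse and connection tables.

    Synapses below ``confidence_min`` are dropped on load.
    """
    neurons = _validate(pd.read_csv(neurons_path), "neurons", neurons_path)
    synapses = _validate(pd.read_csv(synapses_path), "synapses", synapses_path)
    connections = _validate(pd.read_csv(connections_path), "connections", connections_path)
    synapses = synapses[synapses["confidence"] >= confidence_min].reset_index(drop=True)
    return neurons, synapses, connections


def write_tables(neurons, synapses, connections, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "neurons": out / "neurons.csv",
        "synapses": out / "synapses.csv",
        "connections": out / "connections.csv",
    }
    neurons.to_csv(paths["neurons"], index=False)
    synapses.to_csv(paths["synapses"], index=False)
    connections.to_csv(paths["connections"], index=False)
    return paths


@dataclass
class Skeleton:
    """Tree-structured SWC skeleton (nodes with radii and parent links)."""

    nodes: pd.DataFrame  # node_id, structure, x, y, z, radius, parent

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int((self.nodes["parent"] != -1).sum())


def read_swc(path) -> Skeleton:
    """Parse a standard SWC file (7 whitespace-delimited columns, # comments).

    Roots have parent -1; parent links must reference existing nodes and be
    acyclic.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCFormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[4]), float(parts[5]), int(parts[6]))
                )
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise SWCFormatError(f"{path}: empty skeleton (no node lines)")
    nodes = pd.DataFrame(rows, columns=["node_id", "structure", "x", "y", "z", "radius", "parent"])
    ids = set(nodes["node_id"])
    if len(ids) != len(nodes):
        raise SWCFormatError(f"{path}: duplicate node ids")
    parent = dict(zip(nodes["node_id"], nodes["parent"]))
    for nid, par in parent.items():
        if par != -1 and par not in ids:
            raise SWCFormatError(f"{path}: node {nid} has unknown parent {par}")
    for nid in parent:  # cycle check by walking to a root
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise SWCFormatError(f"{path}: cyclic parent links at node {nid}")
            seen.add(cur)
            cur = parent[cur]
    return Skeleton(nodes)


def write_swc(skeleton: Skeleton, path) -> None:
    with open(path, "w") as fh:
        fh.write("# node_id structure x y z radius parent\n")
        for r in skeleton.nodes.itertuples(index=False):
            fh.write(f"{r.node_id} {r.structure} {r.x} {r.y} {r.z} {r.radius} {r.parent}\n")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults follow the study presets.

    Lengths are nm internally; ``distance_threshold_um`` is accepted in um
    and converted where used, because thresholds of that scale are easier
    to state in um.
    """

    seed: int = 0
    # synthetic volume
    n_rings: int = 3
    spacing_nm: float = 5_000.0
    curvature: float = 0.0
    depth_nm: float = 40_000.0
    jitter_sigma_nm: float | None = None  # default: spacing / 6
    # synapse loading
    confidence_min: float = DEFAULT_CONFIDENCE_MIN
    # coordinate bootstrap
    coord_iterations: int = 3
    # pins (medulla preset)
    f_lat: float = 2.0
    n_pc: int = 800
    n_avg: int = 260
    n_tang: int = 7
    n_samp: int = 121
    # layers
    frac_peaks: float = 0.85
    # clustering
    n_clusters: int = 5
    cluster_metric: str = "cosine"
    # morphology features
    morph_confidence_min: float = 0.9
    # matching
    distance_threshold_um: float = 8.0
    # trimming fallbacks
    trim_min_fraction: float = 0.775
    trim_target_fraction: float = 0.995
    # neurotransmitter thresholds
    nt_cell_min_presynapses: int = 50
    nt_type_min_presynapses: int = 100
    nt_min_confidence: float = 0.5
    # inter-region
    cumulative_cut: float = 0.9375

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
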
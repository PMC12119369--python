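"""Layer boundaries from 1D synapse-depth distributions of marker types.

Layers subdivide a neuropil along the pin depth axis.  Each boundary is the
lower or upper cut-off of a peak in the presynapse or postsynapse depth
distribution of a marker cell type; the cut-off level is set implicitly by
requiring that a fraction ``frac_peaks`` of the distribution mass lies
above it.  In lobula-plate mode each boundary is the mean of two
marker-derived thresholds (the marker types leave gaps in depth there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidDepthError, InvalidParameterError, MarkerResolutionError

__all__ = [
    "FRAC_PEAKS",
    "DepthDistribution",
    "LayerScheme",
    "MarkerSpec",
    "depth_distribution",
    "syn_threshold",
    "find_peak_cutoffs",
    "build_layer_scheme",
    "assign_layer",
    "assign_layers",
]

#: per-neuropil peak-mass fractions used to set the cut-off level
FRAC_PEAKS = {"medulla": 0.85, "lobula": 0.80, "lobula_plate": 0.75}


@dataclass
class DepthDistribution:
    """Synapse counts of one cell type over the depth stations of a neuropil."""

    cell_type: str
    neuropil: str
    polarity: str  # "pre" or "post"
    bins: np.ndarray
    subsampled: bool = False

    @property
    def empty(self) -> bool:
        return self.bins.sum() == 0


@dataclass
class LayerScheme:
    """Named layers of a neuropil as strictly increasing depth thresholds.

    ``boundaries`` are interior thresholds in (0, 1); together with 0 and 1
    they partition the unit depth interval into ``len(names)`` layers.
    """

    neuropil: str
    boundaries: np.ndarray
    names: list[str]

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) and ((b <= 0).any() or (b >= 1).any() or (np.diff(b) <= 0).any()):
            raise InvalidParameterError("boundaries must be strictly increasing within (0, 1)")
        if len(self.names) != len(b) + 1:
            raise InvalidParameterError("need exactly one more layer name than boundaries")
        self.boundaries = b


@dataclass(frozen=True)
class MarkerSpec:
    """Which peak cut-off of which marker distribution defines a boundary."""

    cell_type: str
    polarity: str
    peak: int  # 0-based peak index in ascending depth
    side: str  # "lower" or "upper"


def depth_distribution(
    depths: np.ndarray,
    n_samp: int,
    cell_type: str = "",
    neuropil: str = "",
    polarity: str = "pre",
    subsample: bool = False,
) -> DepthDistribution:
    """Histogram of assigned depths over the pin depth stations.

    Depths in [0, 1] are mapped back to their nearest station index;
    ``subsample`` merges adjacent station pairs, halving the resolution
    (121 stations -> 61 bins).  An empty input yields an all-zero
    distribution flagged via :attr:`DepthDistribution.empty`.
    """
    d = np.asarray(depths, dtype=float)
    station = np.rint(d * (n_samp - 1)).astype(int)
    bins = np.bincount(station, minlength=n_samp).astype(float) if len(d) else np.zeros(n_samp)
    if subsample:
        n_sub = (n_samp + 1) // 2
        sub = np.zeros(n_sub)
        sub += bins[0::2]
        sub[: len(bins[1::2])] += bins[1::2]
        bins = sub
    return DepthDistribution(cell_type, neuropil, polarity, bins, subsampled=subsample)


def syn_threshold(bins: np.ndarray, frac_peaks: float) -> float:
    """Implicit cut-off level: the largest level with >= frac_peaks of the
    distribution mass in bins strictly above it."""
    if not 0 < frac_peaks < 1:
        raise InvalidParameterError("frac_peaks must lie in (0, 1)")
    b = np.asarray(bins, dtype=float)
    total = b.sum()
    if total <= 0:
        return 0.0
    best = 0.0
    for level in np.unique(np.concatenate([[0.0], b])):
        if b[b > level].sum() / total >= frac_peaks:
            best = float(level)
    return best


def find_peak_cutoffs(
    dist: DepthDistribution | np.ndarray,
    frac_peaks: float,
    min_separation: int = 3,
) -> list[tuple[int, int | None]]:
    """Lower/upper cut-off station indices of each above-threshold peak.

    Scanning depths in ascending order, an up-crossing of the threshold
    records a lower cut-off and the subsequent down-crossing an upper
    cut-off; successive cut-offs must be at least ``min_separation`` depth
    points apart, so peaks separated by less than that merge.  A peak still
    above threshold at the end of the distribution has upper cut-off
    ``None``.  A distribution entirely at or below the threshold yields no
    peaks.
    """
    bins = dist.bins if isinstance(dist, DepthDistribution) else np.asarray(dist, dtype=float)
    thr = syn_threshold(bins, frac_peaks)
    cuts: list[int] = []
    inside = False
    for i, v in enumerate(bins):
        if not inside and v > thr:
            if cuts and i - cuts[-1] < min_separation:
                cuts.pop()  # reopening too close to the previous upper cut-off: merge
            else:
                cuts.append(i)
            inside = True
        elif inside and v <= thr:
            if i - cuts[-1] < min_separation:
                continue  # upper cut-off must be >= min_separation past the lower
            cuts.append(i)
            inside = False
    pairs: list[tuple[int, int | None]] = []
    for j in range(0, len(cuts), 2):
        pairs.append((cuts[j], cuts[j + 1] if j + 1 < len(cuts) else None))
    return pairs


def _resolve_marker(
    spec: MarkerSpec,
    dists: dict[tuple[str, str], DepthDistribution],
    frac_peaks: float,
) -> float:
    key = (spec.cell_type, spec.polarity)
    if key not in dists:
        raise MarkerResolutionError(f"no depth distribution for marker {spec}")
    dist = dists[key]
    pairs = find_peak_cutoffs(dist, frac_peaks)
    if spec.peak >= len(pairs):
        raise MarkerResolutionError(
            f"marker {spec}: distribution has only {len(pairs)} peak(s)"
        )
    lo, hi = pairs[spec.peak]
    idx = lo if spec.side == "lower" else hi
    if idx is None:
        raise MarkerResolutionError(f"marker {spec}: peak has no upper cut-off")
    n_bins = len(dist.bins)
    return idx / (n_bins - 1)


def build_layer_scheme(
    marker_specs: Sequence,
    dists: dict[tuple[str, str], DepthDistribution],
    neuropil: str,
    layer_names: Sequence[str],
    frac_peaks: float | None = None,
    lobula_plate_mode: bool = False,
) -> LayerScheme:
    """Layer scheme from marker-derived peak cut-offs.

    Each element of ``marker_specs`` defines one boundary: a single
    :class:`MarkerSpec`, or (in ``lobula_plate_mode``) a pair of specs
    whose resolved thresholds are averaged.  Boundaries are sorted
    ascending before the scheme is assembled.
    """
    if frac_peaks is None:
        frac_peaks = FRAC_PEAKS.get(neuropil, 0.85)
    thresholds = []
    for spec in marker_specs:
        if lobula_plate_mode:
            if not (isinstance(spec, (tuple, list)) and len(spec) == 2):
                raise MarkerResolutionError(
                    "lobula-plate mode requires a pair of marker specs per boundary"
                )
            a = _resolve_marker(spec[0], dists, frac_peaks)
            b = _resolve_marker(spec[1], dists, frac_peaks)
            thresholds.append((a + b) / 2.0)
        else:
            thresholds.append(_resolve_marker(spec, dists, frac_peaks))
    return LayerScheme(neuropil, np.sort(np.asarray(thresholds)), list(layer_names))


def assign_layer(depth: float, scheme: LayerScheme) -> str:
    """Layer containing ``depth`` under the half-open [b_k, b_{k+1}) rule.

    A depth exactly on a boundary belongs to the deeper layer; depth 1.0
    maps to the last layer.
    """
    if not 0.0 <= depth <= 1.0:
        raise InvalidDepthError(f"depth {depth} outside [0, 1]")
    return scheme.names[int(np.searchsorted(scheme.boundaries, depth, side="right"))]


def assign_layers(depths: np.ndarray, scheme: LayerScheme) -> np.ndarray:
    """Vectorized :func:`assign_layer`."""
    d = np.asarray(depths, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise InvalidDepthError("depths outside [0, 1]")
    idx = np.searchsorted(scheme.boundaries, d, side="right")
    return np.asarray(scheme.names, dtype=object)[idx]
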
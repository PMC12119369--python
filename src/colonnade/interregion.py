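"""Weighted region-to-region connectivity contributions ("projectome").

A neuron that receives inputs in region A and sends outputs to region C
contributes to the A -> C connectivity the product of its output-connection
count in C and its fraction of input connections in A:

    contribution(A -> C) = outputs[C] * inputs[A] / sum_B inputs[B]

Summing a neuron's contributions over sources therefore reproduces its
output count per target exactly (column conservation), and aggregation
over a neuron group is simple element-wise addition.  A connection belongs
to the region of its postsynaptic site on both the input and output side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "DEFAULT_CUMULATIVE_CUT",
    "DEFAULT_BANDS",
    "neuron_contribution",
    "RegionMatrix",
    "aggregate_group",
    "rank_and_bin",
]

DEFAULT_CUMULATIVE_CUT = 0.9375
#: halving cumulative-share bands used for binning shown connections
DEFAULT_BANDS = (0.5, 0.75, 0.875, 0.9375)


def neuron_contribution(
    inputs_by_region: Mapping[str, float],
    outputs_by_region: Mapping[str, float],
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Contribution matrix (source region x target region) of one neuron.

    A neuron with zero total inputs contributes nothing (all-zero matrix,
    flagged with a warning): it relays no regional input signal.
    """
    ins = pd.Series(inputs_by_region, dtype=float)
    outs = pd.Series(outputs_by_region, dtype=float)
    if (ins < 0).any() or (outs < 0).any():
        raise InvalidParameterError("connection counts must be nonnegative")
    if regions is None:
        regions = sorted(set(ins.index) | set(outs.index))
    ins = ins.reindex(regions, fill_value=0.0)
    outs = outs.reindex(regions, fill_value=0.0)
    total_in = ins.sum()
    if total_in == 0:
        warnings.warn("neuron has zero input connections; zero contribution", stacklevel=2)
        frac = ins * 0.0
    else:
        frac = ins / total_in
    M = pd.DataFrame(np.outer(frac.to_numpy(), outs.to_numpy()),
                     index=pd.Index(regions, name="source"),
                     columns=pd.Index(regions, name="target"))
    return M


@dataclass
class RegionMatrix:
    """Aggregated region-to-region contributions of a neuron group."""

    group: str
    regions: list[str]
    matrix: pd.DataFrame


def aggregate_group(
    neuron_io: Sequence[tuple[Mapping[str, float], Mapping[str, float]]],
    regions: Sequence[str] | None = None,
    group: str = "",
) -> RegionMatrix:
    """Element-wise sum of per-neuron contributions over a group.

    ``neuron_io`` yields (inputs_by_region, outputs_by_region) pairs.
    Regions absent from the region list are accumulated under a catch-all
    ``unmapped`` region with a warning.
    """
    if regions is None:
        names = set()
        for ins, outs in neuron_io:
            names |= set(ins) | set(outs)
        regions = sorted(names)
    regions = list(regions)
    known = set(regions)
    index = regions
    total = pd.DataFrame(0.0, index=pd.Index(index, name="source"),
                         columns=pd.Index(index, name="target"))
    warned = False
    for ins, outs in neuron_io:
        ins = dict(ins)
        outs = dict(outs)
        for d in (ins, outs):
            stray = [r for r in d if r not in known]
            if stray:
                if not warned:
                    warnings.warn(
                        f"connections in unmapped region(s) {stray}: counted under 'unmapped'",
                        stacklevel=2,
                    )
                    warned = True
                if "unmapped" not in total.index:
                    total.loc["unmapped"] = 0.0
                    total["unmapped"] = 0.0
                    known.add("unmapped")
                    regions = regions + ["unmapped"]
                for r in stray:
                    d["unmapped"] = d.get("unmapped", 0.0) + d.pop(r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            M = neuron_contribution(ins, outs, regions=list(total.index))
        total = total.add(M, fill_value=0.0)
    return RegionMatrix(group=group, regions=list(total.index), matrix=total)


def rank_and_bin(
    matrix: pd.DataFrame,
    cumulative_cut: float = DEFAULT_CUMULATIVE_CUT,
    bands: Sequence[float] = DEFAULT_BANDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank entries by contribution, keep the leading cumulative share, bin.

    Entries are sorted descending; those within the leading
    ``cumulative_cut`` of total mass are kept and labelled with the index
    of the cumulative-share band they fall into (0 for the first 50%, 1
    for 50-75%, ...).  Returns (binned matrix with -1 for dropped/zero
    entries, boolean keep mask).
    """
    if not 0 < cumulative_cut <= 1:
        raise InvalidParameterError("cumulative_cut must lie in (0, 1]")
    vals = matrix.to_numpy(dtype=float)
    flat = vals.ravel()
    order = np.argsort(-flat, kind="stable")
    total = flat.sum()
    binned = np.full(flat.shape, -1, dtype=int)
    mask = np.zeros(flat.shape, dtype=bool)
    if total > 0:
        csum = np.cumsum(flat[order]) / total
        eps = 1e-12
        for rank_pos, j in enumerate(order):
            if flat[j] <= 0:
                break
            share = csum[rank_pos]
            if share > cumulative_cut + eps:
                break
            mask[j] = True
            binned[j] = int(np.searchsorted(np.asarray(bands), share - eps, side="left"))
    shape = vals.shape
    return (
        pd.DataFrame(binned.reshape(shape), index=matrix.index, columns=matrix.columns),
        pd.DataFrame(mask.reshape(shape), index=matrix.index, columns=matrix.columns),
    )
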
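"""Per-cell, per-type and consensus neurotransmitter calls, and fan-out.

Per-synapse classifier probabilities over the seven fly transmitters
(ACh, Glu, GABA, His, Dop, OA, 5HT) are aggregated upward: a neuron is
called with its most frequent presynaptic transmitter when it has at least
50 presynapses and the modal fraction (the confidence) reaches 0.5; a cell
type is called the same way over the pooled presynapses of all its neurons
at thresholds 100 / 0.5.  Consensus calls additionally require aminergic
predictions (Dop, OA, 5HT) to be backed by experimental evidence — these
classes are under-represented in classifier training data — otherwise the
type is set to ``unclear``.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TRANSMITTERS",
    "AMINERGIC",
    "UNCLEAR",
    "NTCall",
    "cell_call",
    "type_call",
    "consensus_call",
    "fanout",
]

TRANSMITTERS = ("ACh", "Glu", "GABA", "His", "Dop", "OA", "5HT")
AMINERGIC = frozenset({"Dop", "OA", "5HT"})
UNCLEAR = "unclear"

CELL_MIN_PRESYNAPSES = 50
TYPE_MIN_PRESYNAPSES = 100
MIN_CONFIDENCE = 0.5


class NTCall(NamedTuple):
    call: str
    confidence: float
    n_presynapses: int


def _aggregate(
    probs: pd.DataFrame,
    min_presynapses: int,
    min_confidence: float,
    method: str,
) -> NTCall:
    """Shared call logic.

    ``method='argmax'`` (default): confidence is the modal fraction of the
    per-synapse argmax classes.  ``method='mean_prob'``: confidence is the
    maximum of the synapse-averaged probability vector.  A modal tie cannot
    name a unique most-frequent transmitter and yields ``unclear``.
    """
    cols = [c for c in probs.columns if c in TRANSMITTERS]
    P = probs[cols].to_numpy(dtype=float)
    n = len(P)
    if n == 0:
        return NTCall(UNCLEAR, float("nan"), 0)
    if method == "argmax":
        winners = np.argmax(P, axis=1)
        counts = np.bincount(winners, minlength=len(cols))
        top = counts.max()
        tied = (counts == top).sum() > 1
        call = cols[int(np.argmax(counts))]
        conf = top / n
        if tied:
            return NTCall(UNCLEAR, conf, n)
    elif method == "mean_prob":
        mean = P.mean(axis=0)
        call = cols[int(np.argmax(mean))]
        conf = float(mean.max())
    else:
        raise ValueError(f"unknown confidence method {method!r}")
    if n < min_presynapses or conf < min_confidence:
        return NTCall(UNCLEAR, conf, n)
    return NTCall(call, float(conf), n)


def cell_call(
    presynapse_probs: pd.DataFrame,
    min_presynapses: int = CELL_MIN_PRESYNAPSES,
    min_confidence: float = MIN_CONFIDENCE,
    method: str = "argmax",
) -> NTCall:
    """Neuron-level call from the probability rows of its presynapses."""
    return _aggregate(presynapse_probs, min_presynapses, min_confidence, method)


def type_call(
    pooled_presynapse_probs: pd.DataFrame,
    min_presynapses: int = TYPE_MIN_PRESYNAPSES,
    min_confidence: float = MIN_CONFIDENCE,
    method: str = "argmax",
) -> NTCall:
    """Type-level call over the pooled presynapses of all its neurons."""
    return _aggregate(pooled_presynapse_probs, min_presynapses, min_confidence, method)


def consensus_call(type_result: NTCall | str, experimental_support=None) -> str:
    """Consensus transmitter: the type call, with the aminergic override.

    ``experimental_support`` is the set of experimentally supported
    transmitters for the type (it may carry several, e.g. co-transmission),
    or None when no experimental data exist.  Aminergic calls without
    matching support become ``unclear``; a call never upgrades from
    unclear.
    """
    call = type_result.call if isinstance(type_result, NTCall) else str(type_result)
    if call == UNCLEAR:
        return UNCLEAR
    if call in AMINERGIC:
        support = set(experimental_support or ())
        if call not in support:
            return UNCLEAR
    return call


def fanout(output_connections: np.ndarray, presynapses: np.ndarray) -> float:
    """Type-level synaptic fan-out: per-cell output-connections/presynapses
    ratio, averaged over the cells of the type.

    Fly presynapses are polyadic (one T-bar, several postsynaptic
    partners), so the ratio exceeds 1 and measures how broadly each release
    site is shared.  Cells with zero presynapses are excluded with a
    warning.
    """
    out = np.asarray(output_connections, dtype=float)
    pre = np.asarray(presynapses, dtype=float)
    ok = pre > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} cell(s) with zero presynapses",
                      stacklevel=2)
    if not ok.any():
        return float("nan")
    return float(np.mean(out[ok] / pre[ok]))
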
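"""Shared fixtures: one seeded synthetic volume and its derived products.

Session-scoped so the expensive stages (pin construction over 37 columns)
run once for the whole suite.
"""

import pytest

from colonnade import hexgrid, pins as pinmod
from colonnade.synthetic import DEFAULT_DEPTH_NM, default_volume

SEED = 7


@pytest.fixture(scope="session")
def volume():
    return default_volume(seed=SEED)


@pytest.fixture(scope="session")
def planted_axes(volume):
    """Straight proto-axes fitted to the planted polylines."""
    return [
        hexgrid.compute_proto_axis(volume.grid.axes[c], c) for c in volume.grid.coords
    ]


@pytest.fixture(scope="session")
def neuron_coords(volume, planted_axes):
    return hexgrid.assign_neurons(volume.synapses, planted_axes)


@pytest.fixture(scope="session")
def assigned_synapses(volume, neuron_coords):
    """Synapse table carrying the (p, q) of the owning neuron."""
    return volume.synapses.merge(
        neuron_coords[["p", "q"]], left_on="neuron_id", right_index=True
    )


@pytest.fixture(scope="session")
def medulla():
    return pinmod.Neuropil.slab("medulla", 0.0, DEFAULT_DEPTH_NM)


@pytest.fixture(scope="session")
def built_pins(assigned_synapses, medulla, volume):
    built, rejected = pinmod.build_pins(assigned_synapses, medulla, pinmod.MEDULLA)
    assert not rejected
    return pinmod.regularize_and_fill(built, coords=volume.grid.coords)


@pytest.fixture(scope="session")
def depth_table(volume, built_pins):
    """Per-synapse (column, depth) from nearest-pin assignment."""
    coords, depths = pinmod.assign_points(
        volume.synapses[["x", "y", "z"]].to_numpy(dtype=float), built_pins
    )
    out = volume.synapses[
        ["neuron_id", "polarity", "confidence", "true_p", "true_q", "true_depth"]
    ].copy()
    out["p"] = [c.p for c in coords]
    out["q"] = [c.q for c in coords]
    out["depth"] = depths
    return out
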
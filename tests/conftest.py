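from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stimplast.netsim.network import Network
from stimplast.netsim.params import CellParams, PopulationSpec, default_config

SIMPLE_CELL = dict(
    tau_receptor={"AMPA": 5.0, "NMDA": 40.0, "GABA_A": 10.0},
    reversal={"AMPA": 1.0, "NMDA": 1.0, "GABA_A": -1.0},
    v_threshold=10.0,
    v_block=40.0,
    refrac_abs=2.5,
    refrac_R=6.0,
    tau_R=8.0,
    refrac_H=4.0,
    tau_H=15.0,
)


def make_micro_network(
    n_neurons: int,
    synapses: list[dict],
    cell: dict | None = None,
    stdp: dict | None = None,
) -> Network:
    """Hand-built network of identical cells for engine-level tests.

    ``synapses``: dicts with pre, post, channel, weight, delay and an
    optional ``plastic`` flag.
    """
    cell = dict(cell or SIMPLE_CELL)
    cfg = default_config()
    cfg["stdp"].update(stdp or {})
    params = CellParams(**cell)
    # a single stand-in population spec repeated to satisfy invariants
    spec = PopulationSpec(
        name="test_cells", count_per_495=495, excitatory=True,
        layer="L4", params=params,
    )
    chan_index = {"AMPA": 0, "NMDA": 1, "GABA_A": 2}
    syn = {k: [] for k in ("pre", "post", "ch", "w", "d", "pl")}
    for s in synapses:
        syn["pre"].append(s["pre"])
        syn["post"].append(s["post"])
        syn["ch"].append(chan_index[s["channel"]])
        syn["w"].append(s["weight"])
        syn["d"].append(s["delay"])
        syn["pl"].append(s.get("plastic", False))
    weights = np.asarray(syn["w"], dtype=float)
    net = Network.__new__(Network)
    net.config = cfg
    net.rng_seed = 0
    net.sheet_extent = 1000.0
    net.positions = np.zeros((n_neurons, 2))
    net.pop_of = np.zeros(n_neurons, dtype=np.int64)
    net.population_specs = [spec]
    net.excitatory = np.ones(n_neurons, dtype=bool)
    net.syn_pre = np.asarray(syn["pre"], dtype=np.int64)
    net.syn_post = np.asarray(syn["post"], dtype=np.int64)
    net.syn_channel = np.asarray(syn["ch"], dtype=np.int64)
    net.syn_weight = weights.copy()
    net.syn_weight_baseline = weights.copy()
    net.syn_delay = np.asarray(syn["d"], dtype=float)
    net.syn_plastic = np.asarray(syn["pl"], dtype=bool)
    net.meta = {}
    return net


@pytest.fixture(scope="session")
def small_network():
    """A scale-1 network with the default configuration."""
    from stimplast.netsim import build_network

    cfg = default_config()
    cfg["scale"] = 1
    return build_network(cfg, seed=42)
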
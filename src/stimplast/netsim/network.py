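"""Network construction: cell placement and distance-dependent wiring."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    CHANNELS,
    CellParams,
    ConnRule,
    PopulationSpec,
    cell_params_from_config,
)

BASE_COUNT = 495  # population counts are defined per this many cells


def euclidean_distance(a, b) -> float:
    """Planar distance (um) between two cell positions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("positions must be finite")
    return float(np.hypot(*(a - b))) if a.ndim == 1 else np.hypot(
        a[..., 0] - b[..., 0], a[..., 1] - b[..., 1]
    )


def connection_probability(d, rule: ConnRule):
    """Exponentially decaying connection probability p_max * exp(-d/falloff)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    p = rule.p_max * np.exp(-d / rule.falloff)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class Neuron:
    """Read-only structural view of one cell."""

    id: int
    population: str
    position: tuple[float, float]
    excitatory: bool


@dataclass(frozen=True)
class Synapse:
    """Read-only structural view of one connection."""

    pre: int
    post: int
    channel: str
    weight: float
    weight_baseline: float
    delay: float
    plastic: bool


@dataclass
class Network:
    """Structural state of the model, stored as flat arrays.

    ``syn_weight`` is mutated by plasticity during simulation; all other
    arrays are fixed at build time.
    """

    config: dict
    rng_seed: int
    sheet_extent: float
    positions: np.ndarray  # (n, 2) um
    pop_of: np.ndarray  # (n,) index into population_specs
    population_specs: list[PopulationSpec]
    excitatory: np.ndarray  # (n,) bool
    # synapse table
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_channel: np.ndarray  # index into CHANNELS
    syn_weight: np.ndarray
    syn_weight_baseline: np.ndarray
    syn_delay: np.ndarray  # ms
    syn_plastic: np.ndarray  # bool
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_synapses(self) -> int:
        return len(self.syn_pre)

    def population_ids(self, name: str) -> np.ndarray:
        for i, spec in enumerate(self.population_specs):
            if spec.name == name:
                return np.flatnonzero(self.pop_of == i)
        raise KeyError(f"no population named {name!r}")

    def population_name(self, neuron_id: int) -> str:
        return self.population_specs[self.pop_of[neuron_id]].name

    def neuron(self, neuron_id: int) -> Neuron:
        spec = self.population_specs[self.pop_of[neuron_id]]
        return Neuron(
            id=int(neuron_id),
            population=spec.name,
            position=tuple(self.positions[neuron_id]),
            excitatory=bool(self.excitatory[neuron_id]),
        )

    def synapse(self, s: int) -> Synapse:
        return Synapse(
            pre=int(self.syn_pre[s]),
            post=int(self.syn_post[s]),
            channel=CHANNELS[self.syn_channel[s]],
            weight=float(self.syn_weight[s]),
            weight_baseline=float(self.syn_weight_baseline[s]),
            delay=float(self.syn_delay[s]),
            plastic=bool(self.syn_plastic[s]),
        )

    def cell_param_arrays(self) -> dict[str, np.ndarray]:
        """Per-neuron membrane parameter vectors, expanded from the
        population table (used by the simulation engine)."""
        n = self.n_neurons
        out = {
            key: np.empty(n)
            for key in (
                "tau_AMPA", "tau_NMDA", "tau_GABA_A",
                "rev_AMPA", "rev_NMDA", "rev_GABA_A",
                "v_threshold", "v_block", "refrac_abs",
                "refrac_R", "tau_R", "refrac_H", "tau_H",
            )
        }
        for i, spec in enumerate(self.population_specs):
            ids = self.pop_of == i
            p: CellParams = spec.params
            for ch in CHANNELS:
                out[f"tau_{ch}"][ids] = p.tau_receptor[ch]
                out[f"rev_{ch}"][ids] = p.reversal[ch]
            out["v_threshold"][ids] = p.v_threshold
            out["v_block"][ids] = p.v_block
            out["refrac_abs"][ids] = p.refrac_abs
            out["refrac_R"][ids] = p.refrac_R
            out["tau_R"][ids] = p.tau_R
            out["refrac_H"][ids] = p.refrac_H
            out["tau_H"][ids] = p.tau_H
        return out


def _population_specs(config: dict) -> list[PopulationSpec]:
    specs = []
    for row in config["populations"]:
        specs.append(
            PopulationSpec(
                name=row["name"],
                count_per_495=int(row["count_per_495"]),
                excitatory=bool(row["excitatory"]),
                layer=row["layer"],
                params=cell_params_from_config(config, row["cell_class"]),
            )
        )
    if len(specs) != 14:
        raise ValueError(f"expected 14 populations, got {len(specs)}")
    total = sum(s.count_per_495 for s in specs)
    if total != BASE_COUNT:
        raise ValueError(f"per-{BASE_COUNT} counts sum to {total}, not {BASE_COUNT}")
    return specs


def build_network(config: dict, seed: int) -> Network:
    """Assemble a network from a configuration mapping.

    Cells are placed uniformly at random on a square sheet per layer and
    wired population-to-population with exponentially distance-decaying
    probability.  Structure is deterministic for a fixed seed.
    """
    scale = config["scale"]
    if not (isinstance(scale, (int, np.integer)) and scale >= 1):
        raise ValueError("scale must be a positive integer")
    specs = _population_specs(config)
    extent = float(config["geometry"]["sheet_extent_um"])
    velocity = float(config["geometry"]["axonal_velocity_um_per_ms"])
    rng = np.random.default_rng(seed)

    counts = [s.count_per_495 * scale for s in specs]
    n = sum(counts)
    pop_of = np.repeat(np.arange(len(specs)), counts)
    positions = rng.uniform(0.0, extent, size=(n, 2))
    excitatory = np.array([specs[i].excitatory for i in pop_of])

    layer_of = {s.name: s.layer for s in specs}
    chan_index = {ch: k for k, ch in enumerate(CHANNELS)}
    ids_of = {
        s.name: np.flatnonzero(pop_of == i) for i, s in enumerate(specs)
    }

    pre_list, post_list, ch_list, w_list, d_list, plast_list = [], [], [], [], [], []
    for row in config["connectivity"]:
        rule = ConnRule(**row)
        pre_ids = ids_of[rule.pre_pop]
        post_ids = ids_of[rule.post_pop]
        if not len(pre_ids) or not len(post_ids):
            continue
        dx = positions[pre_ids, None, 0] - positions[None, post_ids, 0]
        dy = positions[pre_ids, None, 1] - positions[None, post_ids, 1]
        dist = np.hypot(dx, dy)
        p = connection_probability(dist, rule)
        draw = rng.random(p.shape) < p
        if rule.pre_pop == rule.post_pop:
            np.fill_diagonal(draw, False)
        ii, jj = np.nonzero(draw)
        pre = pre_ids[ii]
        post = post_ids[jj]
        pre_list.append(pre)
        post_list.append(post)
        ch_list.append(np.full(len(pre), chan_index[rule.channel], dtype=np.int64))
        w_list.append(np.full(len(pre), rule.init_weight))
        d_list.append(rule.base_delay + dist[ii, jj] / velocity)
        plastic = rule.channel in ("AMPA", "NMDA") and layer_of[rule.post_pop] != "thalamus"
        plast_list.append(np.full(len(pre), plastic))

    def cat(parts, dtype):
        return (
            np.concatenate(parts).astype(dtype)
            if parts
            else np.empty(0, dtype=dtype)
        )

    weights = cat(w_list, float)
    return Network(
        config=config,
        rng_seed=int(seed),
        sheet_extent=extent,
        positions=positions,
        pop_of=pop_of,
        population_specs=specs,
        excitatory=excitatory,
        syn_pre=cat(pre_list, np.int64),
        syn_post=cat(post_list, np.int64),
        syn_channel=cat(ch_list, np.int64),
        syn_weight=weights,
        syn_weight_baseline=weights.copy(),
        syn_delay=cat(d_list, float),
        syn_plastic=cat(plast_list, bool),
    )
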
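"""Model parameters: cell classes, population table, connectivity rules.

The network is a layered thalamocortical microcircuit: two thalamic
populations (excitatory relay cells and the inhibitory reticular shell)
plus, for each of cortical layers 2/3, 4, 5 and 6, pyramidal cells,
fast-spiking interneurons and low-threshold-spiking interneurons — 14
populations in all.  Population sizes are expressed per 495 cells, so a
network is always an integer multiple of 495 neurons (the default scale
of 4 gives 1980).

Membrane and synaptic parameters are expressed relative to rest: a
synaptic event deflects the voltage by ``weight x reversal`` mV, and the
deflection decays with the receptor time constant.  The default values
below are this package's own calibration — chosen so that cortical cells
fire at roughly 3 Hz spontaneously during tactile phases and respond to
touch within the 0-70 ms analysis window — and every one of them can be
overridden through the configuration mapping.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

CHANNELS = ("AMPA", "NMDA", "GABA_A")


@dataclass(frozen=True)
class CellParams:
    """Membrane and refractory parameters of one cell class.

    ``reversal`` entries are signed polarity scales relative to rest
    (positive = depolarizing); time constants are ms, voltages mV.
    """

    tau_receptor: dict  # channel -> ms
    reversal: dict  # channel -> polarity scale (AMPA/NMDA > 0, GABA_A < 0)
    v_threshold: float  # mV above rest
    v_block: float  # depolarization-blockade voltage, mV
    refrac_abs: float  # absolute refractory period, ms
    refrac_R: float  # post-spike threshold increase, mV
    tau_R: float  # its decay time constant, ms
    refrac_H: float  # post-spike hyperpolarization, mV
    tau_H: float  # its decay time constant, ms

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if self.tau_receptor.get(ch, 1.0) <= 0:
                raise ValueError(f"non-positive time constant for {ch}")
        if not (self.reversal["GABA_A"] < 0 < self.reversal["AMPA"]):
            raise ValueError("GABA_A must be hyperpolarizing, AMPA depolarizing")
        if self.v_block <= self.v_threshold:
            raise ValueError("v_block must exceed v_threshold")
        if self.refrac_abs < 0:
            raise ValueError("refrac_abs must be >= 0")
        if self.tau_R <= 0 or self.tau_H <= 0:
            raise ValueError("refractory time constants must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    count_per_495: int
    excitatory: bool
    layer: str  # "thalamus", "L2/3", "L4", "L5", "L6"
    params: CellParams


@dataclass(frozen=True)
class ConnRule:
    """Distance-dependent connection rule between two populations.

    Connection probability is ``p_max * exp(-d / falloff)`` where *d* is
    the planar distance between the two cells in micrometres.
    """

    pre_pop: str
    post_pop: str
    channel: str
    p_max: float
    falloff: float  # um
    init_weight: float  # mV deflection per event at baseline
    base_delay: float = 1.0  # ms, synaptic conduction delay

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")
        if self.falloff <= 0:
            raise ValueError("falloff must be > 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass(frozen=True)
class STDPRule:
    """Rectangular spike-timing-dependent plasticity rule.

    Any pre-input/post-spike pairing with |dt| inside the learning
    window changes the weight by one increment: potentiation when the
    input precedes the spike, depression otherwise.  Weights are
    clamped to [0, wmax_factor x baseline].
    """

    increment_frac: float = 0.002  # increment as a fraction of baseline weight
    window: float = 10.0  # ms
    wmax_factor: float = 5.0
    sign_potentiation_for_pre_before_post: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.increment_frac < 0:
            raise ValueError("increment must be >= 0")


# ---------------------------------------------------------------------------
# default parameter tables
# ---------------------------------------------------------------------------

_PYR = dict(
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
_FS = dict(
    tau_receptor={"AMPA": 3.0, "NMDA": 40.0, "GABA_A": 8.0},
    reversal={"AMPA": 1.0, "NMDA": 1.0, "GABA_A": -1.0},
    v_threshold=10.0,
    v_block=40.0,
    refrac_abs=1.5,
    refrac_R=3.0,
    tau_R=4.0,
    refrac_H=2.0,
    tau_H=10.0,
)
_LTS = dict(_FS, v_threshold=12.0, refrac_abs=2.0)
_RETIC = dict(_FS, v_threshold=11.0)
_RELAY = dict(_PYR, refrac_abs=2.0)

_CELL_CLASSES = {
    "pyramidal": _PYR,
    "fast_spiking": _FS,
    "lts": _LTS,
    "reticular": _RETIC,
    "relay": _RELAY,
}

# name, count per 495, excitatory, layer, cell class
_POPULATION_TABLE = [
    ("reticular", 25, False, "thalamus", "reticular"),
    ("relay", 50, True, "thalamus", "relay"),
    ("L2/3_pyr", 125, True, "L2/3", "pyramidal"),
    ("L2/3_fs", 15, False, "L2/3", "fast_spiking"),
    ("L2/3_lts", 10, False, "L2/3", "lts"),
    ("L4_pyr", 90, True, "L4", "pyramidal"),
    ("L4_fs", 12, False, "L4", "fast_spiking"),
    ("L4_lts", 8, False, "L4", "lts"),
    ("L5_pyr", 65, True, "L5", "pyramidal"),
    ("L5_fs", 10, False, "L5", "fast_spiking"),
    ("L5_lts", 5, False, "L5", "lts"),
    ("L6_pyr", 60, True, "L6", "pyramidal"),
    ("L6_fs", 12, False, "L6", "fast_spiking"),
    ("L6_lts", 8, False, "L6", "lts"),
]

# pre, post, channel, p_max, falloff um, weight mV, base delay ms
_CONNECTIVITY_TABLE = [
    # thalamic loop
    ("relay", "reticular", "AMPA", 0.20, 300.0, 4.0, 1.0),
    ("reticular", "relay", "GABA_A", 0.20, 300.0, 4.0, 1.0),
    # thalamocortical
    ("relay", "L4_pyr", "AMPA", 0.30, 200.0, 6.0, 1.0),
    ("relay", "L4_fs", "AMPA", 0.25, 200.0, 5.0, 1.0),
    ("relay", "L5_pyr", "AMPA", 0.12, 200.0, 4.0, 1.0),
    ("relay", "L6_pyr", "AMPA", 0.12, 200.0, 4.0, 1.0),
    # corticothalamic feedback
    ("L6_pyr", "relay", "AMPA", 0.10, 300.0, 3.0, 1.5),
    ("L6_pyr", "reticular", "AMPA", 0.10, 300.0, 3.0, 1.5),
    # interlaminar feedforward
    ("L4_pyr", "L2/3_pyr", "AMPA", 0.18, 200.0, 5.0, 1.0),
    ("L4_pyr", "L2/3_fs", "AMPA", 0.15, 200.0, 4.0, 1.0),
    ("L2/3_pyr", "L5_pyr", "AMPA", 0.18, 200.0, 5.0, 1.0),
    ("L2/3_pyr", "L5_fs", "AMPA", 0.12, 200.0, 4.0, 1.0),
    ("L5_pyr", "L6_pyr", "AMPA", 0.12, 200.0, 4.0, 1.0),
    ("L5_pyr", "L2/3_pyr", "AMPA", 0.06, 200.0, 3.0, 1.0),
]
# intra-layer motifs replicated for every cortical layer
_INTRALAYER_TABLE = [
    # pre class, post class, channel, p_max, falloff, weight, delay
    ("pyr", "pyr", "AMPA", 0.12, 150.0, 4.0, 1.0),
    ("pyr", "pyr", "NMDA", 0.06, 150.0, 1.5, 1.0),
    ("pyr", "fs", "AMPA", 0.25, 150.0, 4.0, 1.0),
    ("pyr", "lts", "AMPA", 0.15, 150.0, 3.0, 1.0),
    ("fs", "pyr", "GABA_A", 0.30, 150.0, 5.0, 1.0),
    ("fs", "fs", "GABA_A", 0.20, 150.0, 3.0, 1.0),
    ("lts", "pyr", "GABA_A", 0.20, 200.0, 4.0, 1.5),
]


def _full_connectivity_table() -> list[tuple]:
    rows = list(_CONNECTIVITY_TABLE)
    for layer in ("L2/3", "L4", "L5", "L6"):
        for pre_c, post_c, ch, p, fo, w, dly in _INTRALAYER_TABLE:
            rows.append((f"{layer}_{pre_c}", f"{layer}_{post_c}", ch, p, fo, w, dly))
    return rows


def default_config() -> dict:
    """Return the default model configuration as a plain mapping."""
    return copy.deepcopy(
        {
            "scale": 4,
            "geometry": {
                "sheet_extent_um": 1000.0,
                "axonal_velocity_um_per_ms": 1000.0,
            },
            "populations": [
                {
                    "name": name,
                    "count_per_495": n,
                    "excitatory": exc,
                    "layer": layer,
                    "cell_class": cls,
                }
                for name, n, exc, layer, cls in _POPULATION_TABLE
            ],
            "cell_params": copy.deepcopy(_CELL_CLASSES),
            "connectivity": [
                {
                    "pre_pop": a,
                    "post_pop": b,
                    "channel": ch,
                    "p_max": p,
                    "falloff": fo,
                    "init_weight": w,
                    "base_delay": dly,
                }
                for a, b, ch, p, fo, w, dly in _full_connectivity_table()
            ],
            "stdp": {
                "increment_frac": 0.002,
                "window": 10.0,
                "wmax_factor": 5.0,
            },
            "background": {
                # per-neuron Poisson drive keeping the network spontaneously
                # active at the target ~3 Hz cortical rate
                "rate_hz": 25.0,
                "weight": 6.5,
                "channel": "AMPA",
            },
            "stimulus": {
                # forced suprathreshold deflection used for touch drive and
                # microstimulation pulses (refractoriness/blockade still apply)
                "weight": 30.0,
                "touch_fraction": 0.25,
                "microstim_fraction": 0.10,
            },
        }
    )


def cell_params_from_config(config: dict, cell_class: str) -> CellParams:
    raw = config["cell_params"][cell_class]
    return CellParams(**raw)


def load_config(path) -> dict:
    """Load a model configuration from a YAML or JSON file, merged over
    the defaults (shallow for scalars, per-section for mappings)."""
    import yaml

    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
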
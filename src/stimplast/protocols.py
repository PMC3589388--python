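"""Stimulation schedules: touch trains, microstimulation, session assembly.

A session is three phases — tactile testing, conditioning, tactile
testing.  During conditioning the network receives either closed-loop
spike-triggered microstimulation (a pulse a fixed 5 ms after each
reference-unit spike), random microstimulation whose inter-pulse
statistics are moment-matched to a spike-triggered sequence, persistent
touch, or nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("spike_triggered", "random", "persistent_touch", "none")


@dataclass
class StimulationSchedule:
    """Phases, stimulus times and targets for one session.

    Times are seconds from session start; ``trigger_delay`` and
    ``lockout`` are milliseconds.
    """

    phases: list[tuple[str, float, float]]
    touch_events: np.ndarray = field(default_factory=lambda: np.empty(0))
    touch_targets: np.ndarray | None = None
    microstim_pulses: np.ndarray = field(default_factory=lambda: np.empty(0))
    microstim_targets: np.ndarray | None = None
    mode: str = "none"
    reference_unit: int | None = None
    trigger_delay: float = 5.0  # ms
    lockout: float = 0.0  # ms, minimum inter-pulse interval

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        prev = None
        for lbl, a, b in self.phases:
            if b <= a:
                raise ValueError(f"phase {lbl}: inverted interval")
            if prev is not None and not np.isclose(a, prev):
                raise ValueError("phases must be contiguous")
            prev = b
        if self.trigger_delay < 0:
            raise ValueError("trigger_delay must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.phases[-1][2]


def make_touch_schedule(
    duration_s: float,
    mean_period_ms: float = 600.0,
    period_range_ms=(400.0, 800.0),
    seed: int | None = None,
) -> np.ndarray:
    """Touch times with inter-event intervals uniform in the given range.

    The default reproduces the model protocol: a mean period of 600 ms
    ranging 400-800 ms.
    """
    lo, hi = period_range_ms
    if hi < lo:
        raise ValueError("period range inverted")
    if not lo <= mean_period_ms <= hi:
        raise ValueError("mean period outside range")
    if duration_s <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n_max = int(duration_s * 1000.0 / lo) + 2
    intervals = rng.uniform(lo, hi, size=n_max) / 1000.0
    times = np.cumsum(intervals)
    return times[times < duration_s]


def make_experimental_touch_schedule(
    duration_s: float, mean_rate_hz: float = 0.5, seed: int | None = None
) -> np.ndarray:
    """Poisson touch train at the experimental mean rate of 0.5 Hz."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if mean_rate_hz <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n = rng.poisson(mean_rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def touch_target_set(network, fraction: float = 0.25) -> np.ndarray:
    """Relay cells closest to the sheet center that receive touch drive.

    Touch is modelled as suprathreshold drive to the central fraction of
    thalamocortical relay cells — a spatially contiguous receptive
    field.
    """
    try:
        relay = network.population_ids("relay")
    except KeyError:
        raise ValueError("network has no thalamic relay population") from None
    center = np.array([network.sheet_extent / 2.0] * 2)
    d = np.hypot(*(network.positions[relay] - center).T)
    k = int(round(fraction * len(relay)))
    order = np.argsort(d, kind="stable")
    return np.sort(relay[order[:k]])


def microstim_target_set(
    network, fraction: float = 0.10, seed: int | None = None
) -> np.ndarray:
    """Random subset of layer-5 pyramidal cells receiving microstimulation."""
    l5 = network.population_ids("L5_pyr")
    k = int(round(fraction * len(l5)))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(l5, size=k, replace=False))


def spike_triggered_pulses(
    reference_spikes, delay_ms: float = 5.0, refractory_lockout_ms: float = 0.0
) -> np.ndarray:
    """Pulse times: one pulse *delay_ms* after each reference spike.

    An optional lockout suppresses pulses closer than
    ``refractory_lockout_ms`` to the previous delivered pulse.
    """
    ref = np.asarray(reference_spikes, dtype=float)
    if ref.size and np.any(np.diff(ref) < 0):
        raise ValueError("reference spike times must be sorted")
    pulses = ref + delay_ms / 1000.0
    if refractory_lockout_ms <= 0 or pulses.size == 0:
        return pulses
    kept = [pulses[0]]
    for t in pulses[1:]:
        if (t - kept[-1]) * 1000.0 >= refractory_lockout_ms:
            kept.append(t)
    return np.asarray(kept)


def random_pulses_matched(
    reference_pulses,
    duration_s: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Random pulse train whose inter-pulse-interval mean and variance
    match a reference sequence.

    Intervals are drawn from a gamma distribution moment-matched to the
    reference IPIs (the reference protocol states only a mean and a
    variance to match).  Returns times from 0 over the reference span or
    an explicit duration.
    """
    ref = np.asarray(reference_pulses, dtype=float)
    if ref.size < 2:
        raise ValueError("need at least 2 reference pulses")
    ipi = np.diff(ref)
    mean = float(np.mean(ipi))
    var = float(np.var(ipi))
    if duration_s is None:
        duration_s = float(ref[-1] - ref[0])
    rng = np.random.default_rng(seed)
    n_max = int(duration_s / mean * 1.5) + 20
    if var <= 0:
        intervals = np.full(n_max, mean)
    else:
        shape = mean**2 / var
        scale = var / mean
        intervals = rng.gamma(shape, scale, size=n_max)
    times = np.cumsum(intervals)
    while times.size and times[-1] < duration_s:  # pragma: no cover
        extra = (
            np.full(n_max, mean) if var <= 0 else rng.gamma(shape, scale, size=n_max)
        )
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < duration_s]


def pick_reference_unit(
    network, microstim_targets, seed: int | None = None, radius_um: float = 250.0
) -> int:
    """Choose the spike-triggered reference cell.

    Mirrors the experimental choice of a random touch-responsive unit:
    a random cortical pyramidal cell within ``radius_um`` of the sheet
    center (the touch-activated region), excluding microstimulation
    targets.
    """
    rng = np.random.default_rng(seed)
    center = np.array([network.sheet_extent / 2.0] * 2)
    excluded = set(int(i) for i in np.asarray(microstim_targets).ravel())
    candidates = []
    for pop in ("L4_pyr", "L2/3_pyr"):
        ids = network.population_ids(pop)
        d = np.hypot(*(network.positions[ids] - center).T)
        candidates.extend(int(i) for i in ids[d < radius_um] if int(i) not in excluded)
    if not candidates:
        raise ValueError("no candidate reference units near the center")
    return int(rng.choice(sorted(candidates)))


def build_session(
    mode: str,
    durations_s=(100.0, 100.0, 100.0),
    network=None,
    seed: int | None = None,
    trigger_delay_ms: float = 5.0,
    lockout_ms: float = 0.0,
    touch_rate_hz: float | None = None,
) -> StimulationSchedule:
    """Assemble a three-phase session schedule.

    Touch events fill both tactile phases (and the conditioning phase
    for ``persistent_touch``).  For the microstimulation modes a
    reference unit and target sets are designated from the network.
    Conditioning pulses for ``spike_triggered``/``random`` modes are
    generated online during simulation, driven by the reference unit.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    d1, d2, d3 = (float(d) for d in durations_s)
    phases = [
        ("tactile_pre", 0.0, d1),
        ("conditioning", d1, d1 + d2),
        ("tactile_post", d1 + d2, d1 + d2 + d3),
    ]
    rng = np.random.default_rng(seed)

    def touches(duration, sub):
        if touch_rate_hz is not None:
            return make_experimental_touch_schedule(
                duration, touch_rate_hz, seed=int(rng.integers(2**31 - 1))
            )
        return make_touch_schedule(duration, seed=int(rng.integers(2**31 - 1)))

    touch_events = [touches(d1, 0), touches(d3, 2) + d1 + d2]
    if mode == "persistent_touch":
        touch_events.insert(1, touches(d2, 1) + d1)
    touch_events = np.sort(np.concatenate(touch_events))

    touch_targets = microstim_targets = None
    reference = None
    if network is not None:
        stim_cfg = network.config.get("stimulus", {})
        touch_targets = touch_target_set(
            network, stim_cfg.get("touch_fraction", 0.25)
        )
        if mode in ("spike_triggered", "random"):
            microstim_targets = microstim_target_set(
                network,
                stim_cfg.get("microstim_fraction", 0.10),
                seed=int(rng.integers(2**31 - 1)),
            )
            reference = pick_reference_unit(
                network, microstim_targets, seed=int(rng.integers(2**31 - 1))
            )

    return StimulationSchedule(
        phases=phases,
        touch_events=touch_events,
        touch_targets=touch_targets,
        microstim_pulses=np.empty(0),
        microstim_targets=microstim_targets,
        mode=mode,
        reference_unit=reference,
        trigger_delay=trigger_delay_ms,
        lockout=lockout_ms,
    )
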
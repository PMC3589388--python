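"""Event-driven simulation of the integrate-and-fire network.

The membrane voltage of every cell is a sum of per-channel synaptic
contributions, each rising instantaneously on a synaptic event by
``weight x reversal`` and decaying exponentially with the receptor time
constant, minus a decaying post-spike hyperpolarization.  Nothing is
integrated on a clock: state is advanced in closed form from one event
to the next, and a cell can fire only at the moment an event (synaptic
delivery, background kick, touch, or microstimulation pulse) deflects
it.  A spike is emitted when the voltage reaches the effective threshold
(resting threshold plus a decaying post-spike increment) while staying
below the depolarization-blockade voltage, outside the absolute
refractory period.

Plasticity is a rectangular STDP rule: every pre-input/post-spike
pairing within the learning window moves the synaptic weight one
increment up (input before spike) or down (spike before input), clamped
to [0, 5x baseline].

Event ordering is deterministic: simultaneous events are processed as
phase boundaries, then stimulus events, then synaptic deliveries, with
insertion order breaking the remaining ties.
"""

from __future__ import annotations

import heapq
from math import exp, inf

import numpy as np
import pandas as pd

from ..session import Phase, SessionRecording
from .network import Network, Synapse
from .params import CHANNELS, STDPRule, config_hash

# event-kind priorities for simultaneous events
_P_PHASE = 0
_P_STIM = 1
_P_DELIVER = 2
_P_BACKGROUND = 3

_K_PHASE = 0
_K_TOUCH = 1
_K_PULSE = 2
_K_DELIVER = 3
_K_BACKGROUND = 4


def stdp_update(synapse: Synapse, delta_t: float, rule: STDPRule) -> Synapse:
    """Apply one STDP pairing to a synapse view and return the result.

    ``delta_t`` is post-spike time minus pre-input time (ms): positive
    pairings inside the window potentiate, negative ones depress.
    """
    if not synapse.plastic:
        return synapse
    if abs(delta_t) > rule.window:
        return synapse
    inc = rule.increment_frac * synapse.weight_baseline
    sign = 1.0 if delta_t >= 0 else -1.0
    if not rule.sign_potentiation_for_pre_before_post:
        sign = -sign
    w = synapse.weight + sign * inc
    w = min(max(w, 0.0), rule.wmax_factor * synapse.weight_baseline)
    return Synapse(
        pre=synapse.pre,
        post=synapse.post,
        channel=synapse.channel,
        weight=w,
        weight_baseline=synapse.weight_baseline,
        delay=synapse.delay,
        plastic=synapse.plastic,
    )


class EngineState:
    """Mutable dynamical state of a network plus its event queue.

    All times are milliseconds.  The synaptic weight array is shared
    with the :class:`Network`, so weights reflect plasticity after a
    run.
    """

    def __init__(self, network: Network, stdp: STDPRule | None = None):
        self.network = network
        cfg = network.config
        self.stdp = stdp or STDPRule(**cfg.get("stdp", {}))
        n = network.n_neurons
        p = network.cell_param_arrays()
        # per-neuron parameter lists (python lists: fast scalar access)
        self.tau = [p[f"tau_{ch}"].tolist() for ch in CHANNELS]
        self.rev = [p[f"rev_{ch}"].tolist() for ch in CHANNELS]
        self.v_threshold = p["v_threshold"].tolist()
        self.v_block = p["v_block"].tolist()
        self.refrac_abs = p["refrac_abs"].tolist()
        self.R = p["refrac_R"].tolist()
        self.tau_R = p["tau_R"].tolist()
        self.H = p["refrac_H"].tolist()
        self.tau_H = p["tau_H"].tolist()
        # dynamical state
        self.u = [[0.0] * n for _ in CHANNELS]  # per-channel contributions
        self.thr_off = [0.0] * n
        self.hyp_off = [0.0] * n
        self.t_upd = [0.0] * n
        self.last_spike = [-inf] * n
        self.spikes: list[list[float]] = [[] for _ in range(n)]
        # synapse state
        self.syn_w = network.syn_weight  # shared, mutated in place
        self.syn_w0 = network.syn_weight_baseline
        self.syn_inc = self.stdp.increment_frac * self.syn_w0
        self.syn_wmax = self.stdp.wmax_factor * self.syn_w0
        self.syn_post = network.syn_post.tolist()
        self.syn_chan = network.syn_channel.tolist()
        self.syn_delay = network.syn_delay.tolist()
        self.syn_plastic = network.syn_plastic.tolist()
        self.last_pre = np.full(network.n_synapses, -inf)
        # adjacency
        self.efferent: list[list[int]] = [[] for _ in range(n)]
        for s, pre in enumerate(network.syn_pre.tolist()):
            self.efferent[pre].append(s)
        self.afferent_plastic: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(n)
        ]
        plastic_ids = np.flatnonzero(network.syn_plastic)
        if len(plastic_ids):
            order = np.argsort(network.syn_post[plastic_ids], kind="stable")
            plastic_ids = plastic_ids[order]
            posts = network.syn_post[plastic_ids]
            starts = np.searchsorted(posts, np.arange(n + 1))
            for i in range(n):
                self.afferent_plastic[i] = plastic_ids[starts[i]:starts[i + 1]]
        # event queue
        self._queue: list[tuple] = []
        self._seq = 0
        # closed-loop hooks, configured by run_simulation
        self.on_spike = None

    # ------------------------------------------------------------------
    # elementary state updates (the model's update rules)
    # ------------------------------------------------------------------
    def _decay_to(self, i: int, t: float) -> None:
        dt = t - self.t_upd[i]
        if dt > 0.0:
            for c in range(3):
                uc = self.u[c]
                if uc[i] != 0.0:
                    uc[i] *= exp(-dt / self.tau[c][i])
            if self.thr_off[i] != 0.0:
                self.thr_off[i] *= exp(-dt / self.tau_R[i])
            if self.hyp_off[i] != 0.0:
                self.hyp_off[i] *= exp(-dt / self.tau_H[i])
            self.t_upd[i] = t

    def voltage(self, i: int, t: float) -> float:
        """Membrane voltage (mV relative to rest) of neuron *i* at *t*."""
        self._decay_to(i, t)
        return self.u[0][i] + self.u[1][i] + self.u[2][i] - self.hyp_off[i]

    def effective_threshold(self, i: int, t: float) -> float:
        self._decay_to(i, t)
        return self.v_threshold[i] + self.thr_off[i]

    def apply_synaptic_event(self, i: int, channel, weight: float, t: float) -> None:
        """Deflect neuron *i* by ``weight x reversal[channel]`` at time *t*."""
        if isinstance(channel, str):
            try:
                channel = CHANNELS.index(channel)
            except ValueError:
                raise ValueError(f"unknown channel {channel!r}") from None
        if t < self.t_upd[i]:
            raise ValueError("synaptic event earlier than neuron state time")
        self._decay_to(i, t)
        self.u[channel][i] += weight * self.rev[channel][i]

    def check_fire(self, i: int, t: float) -> bool:
        """Emit a spike if the firing condition holds at *t*.

        Fires iff voltage >= effective threshold, voltage < blockade
        voltage, and the absolute refractory period has elapsed.  On a
        spike the refractory dynamics are applied and deliveries are
        scheduled to all efferent synapses.
        """
        if t - self.last_spike[i] <= self.refrac_abs[i]:
            return False
        self._decay_to(i, t)
        v = self.u[0][i] + self.u[1][i] + self.u[2][i] - self.hyp_off[i]
        if v < self.v_threshold[i] + self.thr_off[i] or v >= self.v_block[i]:
            return False
        self._fire(i, t)
        return True

    def _fire(self, i: int, t: float) -> None:
        self.spikes[i].append(t)
        # potentiate afferent plastic synapses with recent pre input
        aff = self.afferent_plastic[i]
        if len(aff):
            recent = (t - self.last_pre[aff]) <= self.stdp.window
            if recent.any():
                sel = aff[recent]
                self.syn_w[sel] = np.minimum(
                    self.syn_w[sel] + self.syn_inc[sel], self.syn_wmax[sel]
                )
        self.apply_refractory(i, t)
        for s in self.efferent[i]:
            self.push(t + self.syn_delay[s], _P_DELIVER, _K_DELIVER, s)
        if self.on_spike is not None:
            self.on_spike(i, t)

    def apply_refractory(self, i: int, t_spike: float) -> None:
        """Post-spike reset: clear synaptic contributions, raise the
        threshold by R and hyperpolarize by H (both decaying)."""
        self._decay_to(i, t_spike)
        self.last_spike[i] = t_spike
        self.u[0][i] = self.u[1][i] = self.u[2][i] = 0.0
        self.thr_off[i] += self.R[i]
        self.hyp_off[i] += self.H[i]

    def schedule_spike_deliveries(self, i: int, t: float) -> list[tuple[int, float]]:
        """Arrival times of a spike of neuron *i* at its efferent synapses."""
        return [(s, t + self.syn_delay[s]) for s in self.efferent[i]]

    def deliver(self, s: int, t: float) -> bool:
        """Process arrival of a presynaptic spike at synapse *s*."""
        i = self.syn_post[s]
        self.apply_synaptic_event(i, self.syn_chan[s], self.syn_w[s], t)
        if self.syn_plastic[s]:
            self.last_pre[s] = t
            dt_post = t - self.last_spike[i]
            if 0.0 < dt_post <= self.stdp.window:
                # post fired before this input arrived: depression
                w = self.syn_w[s] - self.syn_inc[s]
                self.syn_w[s] = w if w > 0.0 else 0.0
        return self.check_fire(i, t)

    def run_events(self, external_events, duration_ms: float) -> list[list[float]]:
        """Drive the network with explicit external synaptic events.

        ``external_events`` is an iterable of ``(t_ms, neuron, channel,
        weight)``; spike deliveries triggered along the way are
        processed in time order interleaved with the external events.
        Returns per-neuron spike-time lists (ms).  Intended for small
        deterministic circuits (tests, probing).
        """
        for t, i, ch, w in sorted(external_events):
            if isinstance(ch, str):
                ch = CHANNELS.index(ch)
            self.push(t, _P_STIM, _K_TOUCH, (i, ch, w))
        while self._queue:
            t, prio, _seq, kind, arg = heapq.heappop(self._queue)
            if t > duration_ms:
                break
            if kind == _K_DELIVER:
                self.deliver(arg, t)
            else:
                i, ch, w = arg
                self.apply_synaptic_event(i, ch, w, t)
                self.check_fire(i, t)
        return self.spikes

    # ------------------------------------------------------------------
    def push(self, t: float, prio: int, kind: int, arg) -> None:
        self._seq += 1
        heapq.heappush(self._queue, (t, prio, self._seq, kind, arg))


def run_simulation(
    network: Network,
    schedule,
    duration_s: float | None = None,
    seed: int = 0,
) -> SessionRecording:
    """Simulate the network under a stimulation schedule.

    Parameters
    ----------
    network
        Built network; its plastic weights are updated in place.
    schedule
        A :class:`~stimplast.protocols.StimulationSchedule`.
    duration_s
        Simulated time; defaults to the schedule's end.
    seed
        Seed for background drive and matched-random pulse generation.

    Returns
    -------
    SessionRecording with one spike train per neuron (times in
    seconds), the stimulus-event log, and phase structure.
    """
    from ..protocols import random_pulses_matched  # deferred: cyclic import

    cfg = network.config
    if duration_s is None:
        duration_s = schedule.phases[-1][2]
    duration = duration_s * 1000.0
    if schedule.phases[-1][2] < duration_s - 1e-9:
        raise ValueError("schedule does not cover the requested duration")

    eng = EngineState(network)
    rng = np.random.default_rng(seed)
    bg = cfg.get("background", {})
    bg_rate = float(bg.get("rate_hz", 0.0))
    bg_weight = float(bg.get("weight", 0.0))
    bg_chan = CHANNELS.index(bg.get("channel", "AMPA"))
    stim_weight = float(cfg["stimulus"]["weight"])
    n = network.n_neurons

    touch_targets = (
        [] if schedule.touch_targets is None else list(schedule.touch_targets)
    )
    ms_targets = (
        [] if schedule.microstim_targets is None else list(schedule.microstim_targets)
    )
    mode = schedule.mode
    ref = schedule.reference_unit
    delay_ms = schedule.trigger_delay
    lockout = schedule.lockout

    cond = next(
        ((a * 1e3, b * 1e3) for lbl, a, b in schedule.phases if lbl == "conditioning"),
        None,
    )
    pre_span = next(
        ((a * 1e3, b * 1e3) for lbl, a, b in schedule.phases if lbl == "tactile_pre"),
        None,
    )

    # pre-load scheduled events
    for lbl, a, b in schedule.phases:
        eng.push(a * 1e3, _P_PHASE, _K_PHASE, lbl)
    for t in np.asarray(schedule.touch_events, dtype=float):
        if t * 1e3 <= duration:
            eng.push(t * 1e3, _P_STIM, _K_TOUCH, None)
    for t in np.asarray(schedule.microstim_pulses, dtype=float):
        if t * 1e3 <= duration:
            eng.push(t * 1e3, _P_STIM, _K_PULSE, None)

    # lazy per-neuron background drive
    if bg_rate > 0.0 and bg_weight != 0.0:
        scale_ms = 1000.0 / bg_rate
        first = rng.exponential(scale_ms, size=n)
        for i in range(n):
            if first[i] <= duration:
                eng.push(first[i], _P_BACKGROUND, _K_BACKGROUND, i)

    last_pulse_time = [-inf]

    if mode == "spike_triggered" and ref is not None and cond is not None:

        def on_spike(i: int, t: float) -> None:
            if i == ref and cond[0] <= t and t + delay_ms < cond[1]:
                if t + delay_ms - last_pulse_time[0] >= lockout:
                    last_pulse_time[0] = t + delay_ms
                    eng.push(t + delay_ms, _P_STIM, _K_PULSE, None)

        eng.on_spike = on_spike

    events_log: list[tuple[float, str, str]] = []
    for lbl, a, b in schedule.phases:
        events_log.append((a, "phase_boundary", lbl))

    queue = eng._queue
    pop = heapq.heappop
    exp_rng = rng.exponential
    while queue:
        t, prio, _seq, kind, arg = pop(queue)
        if t > duration:
            break
        if kind == _K_DELIVER:
            eng.deliver(arg, t)
        elif kind == _K_BACKGROUND:
            eng.apply_synaptic_event(arg, bg_chan, bg_weight, t)
            eng.check_fire(arg, t)
            t_next = t + exp_rng(scale_ms)
            if t_next <= duration:
                eng.push(t_next, _P_BACKGROUND, _K_BACKGROUND, arg)
        elif kind == _K_TOUCH:
            events_log.append((t / 1e3, "touch", ""))
            for i in touch_targets:
                eng.apply_synaptic_event(i, 0, stim_weight, t)
                eng.check_fire(i, t)
        elif kind == _K_PULSE:
            events_log.append((t / 1e3, "microstim_pulse", ""))
            for i in ms_targets:
                eng.apply_synaptic_event(i, 0, stim_weight, t)
                eng.check_fire(i, t)
        elif kind == _K_PHASE:
            if arg == "conditioning" and mode == "random" and ref is not None:
                # statistics-matched random pulses, built from the
                # reference unit's activity in the preceding phase
                ref_spk = [
                    s for s in eng.spikes[ref] if pre_span[0] <= s < pre_span[1]
                ]
                if len(ref_spk) >= 2:
                    pulses = random_pulses_matched(
                        np.asarray(ref_spk) / 1e3,
                        duration_s=(cond[1] - cond[0]) / 1e3,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    for tp in pulses:
                        eng.push(cond[0] + tp * 1e3, _P_STIM, _K_PULSE, None)

    spike_times = {
        i: np.asarray(eng.spikes[i]) / 1e3 for i in range(n)
    }
    events = pd.DataFrame(
        sorted(events_log), columns=["time_s", "event_type", "payload"]
    )
    phases = [Phase(lbl, a, b) for lbl, a, b in schedule.phases]
    rec = SessionRecording(
        spike_times=spike_times,
        events=events,
        phases=phases,
        unit_positions={i: tuple(network.positions[i]) for i in range(n)},
        unit_populations={i: network.population_name(i) for i in range(n)},
        reference_unit=ref,
        seed=int(seed),
        config_hash=config_hash(cfg),
        meta={"mode": mode, "scale": cfg["scale"]},
    )
    return rec
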
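"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's closed-form event-driven code
paths: the membrane model is integrated on a fine fixed time step, and
entropies are computed by exhaustive state enumeration.
"""

from __future__ import annotations

import numpy as np

CHANNELS = ("AMPA", "NMDA", "GABA_A")


def fixed_step_simulate(
    cell_params: dict,
    n_neurons: int,
    synapses: list[dict],
    external_events: list[tuple],
    duration_ms: float,
    dt: float = 0.01,
) -> list[list[float]]:
    """Fixed-step reference integrator for tiny circuits.

    Same model semantics as the event-driven engine (instantaneous-rise
    exponential-decay synaptic contributions, threshold/blockade firing
    checked when an event lands, absolute refractory period, post-spike
    trace reset with threshold and hyperpolarization offsets) but the
    state is advanced by per-step exponential decay factors and event
    times are quantized to the step grid.

    ``external_events``: iterable of (t_ms, neuron, channel_name, weight).
    """
    p = cell_params
    decay_u = [np.exp(-dt / p["tau_receptor"][ch]) for ch in CHANNELS]
    decay_R = np.exp(-dt / p["tau_R"])
    decay_H = np.exp(-dt / p["tau_H"])
    rev = [p["reversal"][ch] for ch in CHANNELS]

    n_steps = int(round(duration_ms / dt))
    u = np.zeros((3, n_neurons))
    thr_off = np.zeros(n_neurons)
    hyp_off = np.zeros(n_neurons)
    last_spike = np.full(n_neurons, -np.inf)
    spikes: list[list[float]] = [[] for _ in range(n_neurons)]

    # event buckets per step
    buckets: dict[int, list[tuple]] = {}
    for t, i, ch, w in external_events:
        k = int(round(t / dt))
        buckets.setdefault(k, []).append((i, CHANNELS.index(ch), w))

    eff = {}
    for s in synapses:
        eff.setdefault(s["pre"], []).append(s)

    for k in range(n_steps + 1):
        t = k * dt
        if k > 0:
            for c in range(3):
                u[c] *= decay_u[c]
            thr_off *= decay_R
            hyp_off *= decay_H
        hit = buckets.pop(k, None)
        if not hit:
            continue
        for i, c, w in hit:
            u[c][i] += w * rev[c]
            if t - last_spike[i] <= p["refrac_abs"]:
                continue
            v = u[0][i] + u[1][i] + u[2][i] - hyp_off[i]
            if v < p["v_threshold"] + thr_off[i] or v >= p["v_block"]:
                continue
            # spike
            spikes[i].append(t)
            last_spike[i] = t
            u[0][i] = u[1][i] = u[2][i] = 0.0
            thr_off[i] += p["refrac_R"]
            hyp_off[i] += p["refrac_H"]
            for s in eff.get(i, []):
                kk = int(round((t + s["delay"]) / dt))
                buckets.setdefault(kk, []).append(
                    (s["post"], CHANNELS.index(s["channel"]), s["weight"])
                )
    return spikes


def enumeration_entropy(columns: np.ndarray) -> float:
    """Joint entropy (bits) of the rows of a (k, n) discrete array,
    computed by explicit enumeration of observed joint states."""
    from collections import Counter

    states = Counter(tuple(col) for col in columns.T)
    n = columns.shape[1]
    return -sum((c / n) * np.log2(c / n) for c in states.values())


def enumeration_mi(x, y) -> float:
    """Mutual information by brute-force joint-state counting."""
    x = np.asarray(x)
    y = np.asarray(y)
    hx = enumeration_entropy(x[None, :])
    hy = enumeration_entropy(y[None, :])
    hxy = enumeration_entropy(np.vstack([x, y]))
    return hx + hy - hxy


def enumeration_total_correlation(rows: np.ndarray) -> float:
    """Multi-information (total correlation) by enumeration."""
    rows = np.asarray(rows)
    return sum(
        enumeration_entropy(rows[m][None, :]) for m in range(rows.shape[0])
    ) - enumeration_entropy(rows)
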
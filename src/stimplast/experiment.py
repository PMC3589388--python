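"""End-to-end experiment orchestration.

``run_experiment`` simulates one three-phase session (or loads one),
analyses the two tactile phases with the full pipeline, and emits the
before/after comparison: PSTH response metrics, stimulus-locked Fano
factor decrease, shuffle-corrected mutual information, multi-
information, pairwise correlation, and the four-way responsiveness
partition.  Analyses operate on a "recorded ensemble" — a patch of
cortical units around the sheet center, emulating a multi-electrode
array — rather than on all simulated cells.
"""

from __future__ import annotations

import numpy as np

from . import infotheory as it
from . import spikestats as ss
from .netsim import build_network, default_config, run_simulation
from .protocols import build_session
from .session import SessionRecording

THALAMIC_POPULATIONS = ("relay", "reticular")


def recorded_units(
    recording: SessionRecording,
    n: int = 42,
    radius_um: float = 250.0,
    seed: int | None = None,
) -> list[int]:
    """Sample the analysis ensemble: cortical units within ``radius_um``
    of the sheet center (the array's footprint), reference unit included.

    Falls back to all cortical units when fewer than ``n`` qualify; for
    recordings without population labels all units are candidates.
    """
    rng = np.random.default_rng(seed)
    units = recording.units
    if recording.unit_populations:
        units = [
            u for u in units
            if recording.unit_populations[u] not in THALAMIC_POPULATIONS
        ]
    if radius_um is not None and recording.unit_positions:
        center = np.array([500.0, 500.0])
        near = [
            u for u in units
            if np.hypot(*(np.asarray(recording.unit_positions[u]) - center))
            < radius_um
        ]
        if len(near) >= min(n, 2):
            units = near
    if len(units) <= n:
        chosen = list(units)
    else:
        chosen = list(rng.choice(units, size=n, replace=False))
    ref = recording.reference_unit
    if ref is not None and ref not in chosen and ref in recording.spike_times:
        chosen[0] = ref
    return sorted(int(u) for u in chosen)


def phase_summary(
    recording: SessionRecording,
    phase: str,
    units,
    bin_ms: float = 10.0,
    n_shuffles: int = 20,
    subensemble_size: int = 5,
    n_subensembles: int = 50,
    seed: int | None = None,
) -> dict:
    """All per-phase analysis quantities for one tactile phase."""
    events = recording.touch_times(phase)
    if events.size == 0:
        raise ValueError(f"phase {phase!r} has no touch events")
    trains = {u: recording.spike_times[u] for u in units}
    unit_metrics = {}
    for u in units:
        psth = ss.compute_psth(trains[u], events)
        unit_metrics[u] = ss.response_metrics(psth)
    ens_psth = ss.ensemble_psth(trains, events)
    ens_metrics = ss.response_metrics(ens_psth)
    fanos = [
        ss.fano_timecourse(ss.align_to_events(trains[u], events, (-250.0, 300.0)))
        for u in units
    ]
    ens_fano = ss.ensemble_fano(fanos)
    c = ens_fano.window_centers
    ff_baseline = float(
        np.nanmean(ens_fano.fano[(c >= -250.0) & (c < 0.0)])
    )
    fano_decrease = ss.fano_stimulus_decrease(ens_fano)
    counts = it.bin_spike_counts(recording, bin_ms=bin_ms, phase=phase, units=units)
    ss_seed = np.random.SeedSequence(seed)
    s_mi, s_multi = ss_seed.spawn(2)
    info = it.mi_matrix(
        counts,
        n_shuffles=n_shuffles,
        seed=np.random.default_rng(s_mi).integers(2**31 - 1),
        positions=recording.unit_positions,
    )
    multi = it.multi_information(
        counts,
        subensemble_size=min(subensemble_size, len(units)),
        n_subensembles=n_subensembles,
        n_shuffles=n_shuffles,
        seed=np.random.default_rng(s_multi).integers(2**31 - 1),
    )
    x = counts.counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    iu = np.triu_indices(len(units), k=1)
    mean_corr = float(np.nanmean(r[iu]))
    return {
        "events": events,
        "unit_metrics": unit_metrics,
        "ensemble_psth": ens_psth,
        "ensemble_metrics": ens_metrics,
        "ensemble_fano": ens_fano,
        "fano_baseline": ff_baseline,
        "fano_decrease_pc": fano_decrease,
        "info": info,
        "mean_mi": it.mean_pair_mi(info),
        "multi_info": multi,
        "mean_correlation": mean_corr,
        "baseline_rate": ens_psth.baseline_mean,
    }


def _pc(before: float, after: float) -> float:
    return 100.0 * (after - before) / before if before else float("nan")


def compare_session(
    recording: SessionRecording,
    units=None,
    seed: int | None = None,
    **kwargs,
) -> dict:
    """Before/after comparison of one session's tactile phases.

    Returns the two phase summaries plus percentage changes for every
    ensemble metric and the responsiveness partition.
    """
    if units is None:
        units = recorded_units(recording, seed=seed)
    s_pre, s_post = np.random.SeedSequence(seed).spawn(2)
    pre = phase_summary(
        recording, "tactile_pre", units,
        seed=np.random.default_rng(s_pre).integers(2**31 - 1), **kwargs,
    )
    post = phase_summary(
        recording, "tactile_post", units,
        seed=np.random.default_rng(s_post).integers(2**31 - 1), **kwargs,
    )
    labels, proportions = ss.classify_responsiveness(
        pre["unit_metrics"], post["unit_metrics"]
    )
    m_pre, m_post = pre["ensemble_metrics"], post["ensemble_metrics"]
    comparison = {
        "units": list(units),
        "pre": pre,
        "post": post,
        "pc": {
            "peak_rate": _pc(m_pre.peak_rate, m_post.peak_rate),
            "auc": _pc(m_pre.auc, m_post.auc),
            "sharpness": _pc(m_pre.sharpness, m_post.sharpness),
            "baseline_rate": _pc(pre["baseline_rate"], post["baseline_rate"]),
            "mean_mi": _pc(pre["mean_mi"], post["mean_mi"]),
            "multi_info": _pc(pre["multi_info"], post["multi_info"]),
            "mean_correlation": _pc(
                pre["mean_correlation"], post["mean_correlation"]
            ),
        },
        "fano_decrease_pre_pc": pre["fano_decrease_pc"],
        "fano_decrease_post_pc": post["fano_decrease_pc"],
        "responsiveness_labels": labels,
        "responsiveness_proportions": proportions,
    }
    return comparison


def run_experiment(
    mode: str = "spike_triggered",
    scale: int = 1,
    durations_s=(30.0, 30.0, 30.0),
    seed: int = 0,
    out_dir=None,
    analyze: bool = True,
    config: dict | None = None,
    n_recorded: int = 42,
) -> tuple[SessionRecording, dict | None]:
    """Simulate one session and (optionally) run the full analysis.

    Seeds for network construction, scheduling, simulation, ensemble
    sampling and analysis are all derived from ``seed``.
    """
    cfg = config or default_config()
    cfg = {**cfg, "scale": scale}
    seeds = np.random.SeedSequence(seed).spawn(4)
    s_net, s_sched, s_sim, s_ana = (
        int(np.random.default_rng(s).integers(2**31 - 1)) for s in seeds
    )
    network = build_network(cfg, seed=s_net)
    schedule = build_session(mode, durations_s=durations_s, network=network,
                             seed=s_sched)
    recording = run_simulation(network, schedule, seed=s_sim)
    results = None
    if analyze:
        units = recorded_units(recording, n=n_recorded, seed=s_ana)
        results = compare_session(recording, units=units, seed=s_ana)
    if out_dir is not None:
        from .io import write_session

        write_session(recording, out_dir)
    return recording, results


def simulation_batch(
    seeds,
    mode: str = "spike_triggered",
    scale: int = 1,
    durations_s=(30.0, 30.0, 30.0),
) -> dict[str, list[float]]:
    """Run one seeded session per entry of ``seeds`` and collect the
    before/after summary metrics used for reproduction checks.

    Returns per-seed lists: ensemble-PSTH peak/AUC/sharpness PCs, mean
    pair-MI and multi-information PCs, pre/post Fano decreases, the
    pre-phase baseline rate, and the responsiveness partition.
    """
    out: dict[str, list[float]] = {
        k: []
        for k in (
            "peak_pc", "auc_pc", "sharpness_pc", "mi_pc", "multi_pc",
            "fano_decrease_pre", "fano_decrease_post", "baseline_rate_hz",
            "prop_always", "prop_before_only", "prop_after_only", "prop_never",
        )
    }
    for seed in seeds:
        _, res = run_experiment(
            mode=mode, scale=scale, durations_s=durations_s, seed=int(seed)
        )
        out["peak_pc"].append(res["pc"]["peak_rate"])
        out["auc_pc"].append(res["pc"]["auc"])
        out["sharpness_pc"].append(res["pc"]["sharpness"])
        out["mi_pc"].append(res["pc"]["mean_mi"])
        out["multi_pc"].append(res["pc"]["multi_info"])
        out["fano_decrease_pre"].append(res["fano_decrease_pre_pc"])
        out["fano_decrease_post"].append(res["fano_decrease_post_pc"])
        out["baseline_rate_hz"].append(res["pre"]["baseline_rate"])
        for cls in ("always", "before_only", "after_only", "never"):
            out[f"prop_{cls}"].append(res["responsiveness_proportions"][cls])
    return out
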
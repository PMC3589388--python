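"""Firing-rate and variability analysis: PSTH, response metrics, Fano factor.

Conventions follow the standard touch-response analysis: peristimulus
time runs from -250 ms to +300 ms around each touch, rates are obtained
by smoothing the trial-averaged histogram with a Gaussian kernel
(sigma = 20 ms), baseline statistics are computed over [-250, 0) ms,
the response window is [0, 70] ms, and a unit is touch-responsive when
its peak rate in the response window exceeds baseline mean + 3 SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASELINE_WINDOW_MS = (-250.0, 0.0)
RESPONSE_WINDOW_MS = (0.0, 70.0)


@dataclass
class PSTHResult:
    """Kernel-smoothed peristimulus rate plus baseline statistics."""

    bin_centers: np.ndarray  # ms, peristimulus
    rate: np.ndarray  # Hz
    n_trials: int
    baseline_mean: float  # Hz, over [-250, 0) ms
    baseline_sd: float  # Hz


@dataclass
class ResponseMetrics:
    peak_rate: float  # Hz
    auc: float  # spikes (area above baseline in the response window)
    sharpness: float  # Hz/ms; NaN when not responsive
    responsive: bool
    latency: float  # ms of the peak
    degenerate_baseline: bool = False


@dataclass
class FanoTimecourse:
    window_centers: np.ndarray  # ms
    fano: np.ndarray  # variance/mean; NaN where mean count is 0
    window: float  # ms
    step: float  # ms
    n_trials: int


def align_to_events(spike_times_s, event_times_s, range_ms) -> list[np.ndarray]:
    """Per-trial spike times in ms relative to each event."""
    spikes = np.asarray(spike_times_s, dtype=float) * 1000.0
    out = []
    for ev in np.asarray(event_times_s, dtype=float) * 1000.0:
        rel = spikes - ev
        out.append(rel[(rel >= range_ms[0]) & (rel < range_ms[1])])
    return out


def compute_psth(
    train,
    events,
    range_ms=(-250.0, 300.0),
    kernel_sigma_ms: float = 20.0,
    bin_ms: float = 1.0,
) -> PSTHResult:
    """Trial-aligned, Gaussian-smoothed peristimulus rate in Hz.

    Parameters
    ----------
    train
        Spike times, seconds.
    events
        Stimulus times, seconds.
    range_ms
        Peristimulus range; must cover the baseline window.
    kernel_sigma_ms
        Gaussian kernel sigma (truncated at +-3 sigma).

    The histogram is accumulated over an internally padded range so
    that, away from the requested edges, the smoothed rate integrates
    to the per-trial spike count.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one stimulus event")
    pad = 3.0 * kernel_sigma_ms
    lo, hi = range_ms
    trials = align_to_events(train, events, (lo - pad, hi + pad))
    edges = np.arange(lo - pad, hi + pad + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for rel in trials:
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(events) * bin_ms / 1000.0)  # Hz per bin
    # normalized Gaussian kernel, truncated at 3 sigma
    half = int(np.ceil(3.0 * kernel_sigma_ms / bin_ms))
    kx = np.arange(-half, half + 1) * bin_ms
    kernel = np.exp(-0.5 * (kx / kernel_sigma_ms) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(rate, kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = (centers >= lo) & (centers < hi)
    centers, smooth = centers[keep], smooth[keep]
    base = (centers >= BASELINE_WINDOW_MS[0]) & (centers < BASELINE_WINDOW_MS[1])
    baseline_mean = float(smooth[base].mean()) if base.any() else 0.0
    baseline_sd = float(smooth[base].std()) if base.any() else 0.0
    return PSTHResult(
        bin_centers=centers,
        rate=smooth,
        n_trials=len(events),
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
    )


def ensemble_psth(trains: dict, events, **kwargs) -> PSTHResult:
    """Ensemble PSTH: mean smoothed rate across units.

    Baseline statistics are recomputed on the ensemble-mean rate, so the
    3 SD responsiveness criterion applies at the population level.
    """
    results = [compute_psth(t, events, **kwargs) for t in trains.values()]
    rate = np.mean([r.rate for r in results], axis=0)
    centers = results[0].bin_centers
    base = (centers >= BASELINE_WINDOW_MS[0]) & (centers < BASELINE_WINDOW_MS[1])
    return PSTHResult(
        bin_centers=centers,
        rate=rate,
        n_trials=results[0].n_trials,
        baseline_mean=float(rate[base].mean()),
        baseline_sd=float(rate[base].std()),
    )


def response_metrics(
    psth: PSTHResult, response_window_ms=RESPONSE_WINDOW_MS
) -> ResponseMetrics:
    """Peak, above-baseline area, sharpness and the 3 SD responsiveness flag."""
    c, r = psth.bin_centers, psth.rate
    lo, hi = response_window_ms
    half = float(np.median(np.diff(c))) / 2.0
    if c[0] - half > BASELINE_WINDOW_MS[0] + 1e-9 or c[-1] + half < hi - 1e-9:
        raise ValueError("PSTH range does not cover baseline and response windows")
    win = (c >= lo) & (c <= hi)
    rw = r[win]
    peak = float(rw.max())
    k_peak = int(np.argmax(rw))
    latency = float(c[win][k_peak])
    dt_s = float(np.median(np.diff(c))) / 1000.0
    auc = float(np.sum(rw - psth.baseline_mean) * dt_s)
    degenerate = psth.baseline_sd == 0.0 and psth.baseline_mean > 0.0
    level = psth.baseline_mean + 3.0 * psth.baseline_sd
    responsive = peak > level if not degenerate else peak > psth.baseline_mean
    sharpness = float("nan")
    if responsive:
        width = _width_at_level(c, r, int(np.flatnonzero(win)[k_peak]), level)
        sharpness = peak / width if width > 0 else float("inf")
    return ResponseMetrics(
        peak_rate=peak,
        auc=auc,
        sharpness=sharpness,
        responsive=bool(responsive),
        latency=latency,
        degenerate_baseline=degenerate,
    )


def _width_at_level(c, r, k_peak, level) -> float:
    """Temporal width (ms) of the response curve at the given level,
    measured at the crossings nearest the peak on each side."""
    left = c[0]
    for k in range(k_peak, 0, -1):
        if r[k - 1] < level <= r[k]:
            # linear interpolation of the crossing
            f = (level - r[k - 1]) / (r[k] - r[k - 1])
            left = c[k - 1] + f * (c[k] - c[k - 1])
            break
    right = c[-1]
    for k in range(k_peak, len(c) - 1):
        if r[k + 1] < level <= r[k]:
            f = (r[k] - level) / (r[k] - r[k + 1])
            right = c[k] + f * (c[k + 1] - c[k])
            break
    return float(right - left)


def fano_timecourse(
    trains_by_trial,
    window_ms: float = 20.0,
    step_ms: float = 3.0,
    range_ms=(-250.0, 300.0),
) -> FanoTimecourse:
    """Sliding-window Fano factor (spike-count variance/mean across trials).

    ``trains_by_trial`` is a sequence of per-trial spike-time arrays in
    ms relative to the stimulus.  Windows of ``window_ms`` are shifted
    in ``step_ms`` increments; windows with zero mean count are NaN.
    """
    trials = [np.asarray(t, dtype=float) for t in trains_by_trial]
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    lo, hi = range_ms
    starts = np.arange(lo, hi - window_ms + 1e-9, step_ms)
    centers = starts + window_ms / 2.0
    counts = np.empty((len(trials), len(starts)))
    for i, t in enumerate(trials):
        t = np.sort(t)
        counts[i] = np.searchsorted(t, starts + window_ms) - np.searchsorted(t, starts)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    return FanoTimecourse(
        window_centers=centers,
        fano=fano,
        window=window_ms,
        step=step_ms,
        n_trials=len(trials),
    )


def ensemble_fano(per_unit: list[FanoTimecourse]) -> FanoTimecourse:
    """Ensemble-average Fano timecourse (NaN windows excluded per unit)."""
    if not per_unit:
        raise ValueError("no units")
    fano = np.nanmean(np.stack([f.fano for f in per_unit]), axis=0)
    f0 = per_unit[0]
    return FanoTimecourse(f0.window_centers, fano, f0.window, f0.step, f0.n_trials)


def fano_stimulus_decrease(
    fano: FanoTimecourse,
    baseline_window_ms=BASELINE_WINDOW_MS,
    response_window_ms=RESPONSE_WINDOW_MS,
) -> float:
    """Percentage decrease of the Fano factor following stimulus onset.

    The stimulus-locked variability decline is transient, so it is
    quantified as the drop from the baseline-window mean FF to the
    post-onset trough (minimum FF within the response window), the
    standard readout of stimulus-driven variability quenching.
    """
    c = fano.window_centers
    base = (c >= baseline_window_ms[0]) & (c < baseline_window_ms[1])
    resp = (c >= response_window_ms[0]) & (c <= response_window_ms[1])
    ff_base = np.nanmean(fano.fano[base])
    ff_trough = np.nanmin(fano.fano[resp])
    return float(100.0 * (ff_base - ff_trough) / ff_base)


RESPONSE_CLASSES = ("always", "before_only", "after_only", "never")


def classify_responsiveness(
    before: dict[int, ResponseMetrics], after: dict[int, ResponseMetrics]
):
    """Four-way classification of units by responsiveness in each phase.

    Returns ``(labels, proportions)`` where labels maps unit id to one
    of ``always`` / ``before_only`` / ``after_only`` / ``never``.
    """
    if set(before) != set(after):
        raise ValueError("unit sets differ between phases")
    labels = {}
    for uid in before:
        b, a = before[uid].responsive, after[uid].responsive
        labels[uid] = (
            "always" if (b and a)
            else "before_only" if b
            else "after_only" if a
            else "never"
        )
    n = len(labels) or 1
    proportions = {
        cls: sum(1 for v in labels.values() if v == cls) / n
        for cls in RESPONSE_CLASSES
    }
    return labels, proportions
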
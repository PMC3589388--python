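"""Synthetic experiment-like sessions with known ground truth.

Emulates the in vivo recordings: an ensemble of ~42 units at ~10 Hz,
touch events at 0.5 Hz, touch-locked Gaussian response bumps at
per-unit latencies inside the 0-70 ms window, super-Poisson count
variability from a slow multiplicative gain process, and pairwise count
correlation induced by a shared Poisson source with per-unit thinning.
A :class:`BeforeAfterEffect` injects exact percentage changes between
the two tactile phases so the analysis pipeline can be validated by
recovery.

Construction notes
------------------
* Each unit's background is ``common + independent`` Poisson processes.
  With thinning probabilities ``q_i = sqrt(c * b_i / b_max)`` of a
  shared source at the maximum background rate, every pair's binned
  count correlation is ``c`` before gain dilution; the generator
  pre-compensates the gain-induced dilution so the *measured*
  correlation at the analysis bin size matches the requested target.
* The gain process multiplies only the independent component, in
  piecewise-constant blocks, giving a baseline Fano factor above 1;
  response bumps are left Poisson, which reproduces the
  stimulus-locked Fano-factor drop seen in cortex.
* The injected peak change is defined on the kernel-smoothed PSTH peak
  (the quantity the pipeline measures), using the closed-form
  attenuation of a Gaussian bump by the analysis kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import make_experimental_touch_schedule
from .session import Phase, SessionRecording

BUMP_SIGMA_MS = 10.0  # temporal width of the touch response
ANALYSIS_KERNEL_SIGMA_MS = 20.0  # PSTH kernel the effects are defined against
GAIN_BLOCK_S = 0.5  # length of one gain block
FANO_WINDOW_MS = 20.0  # window the Fano-factor effect is defined against


@dataclass
class BeforeAfterEffect:
    """Ground-truth percentage changes applied to the post phase."""

    peak_gain_pc: float = 0.0  # % change of the smoothed PSTH peak
    baseline_gain_pc: float = 0.0  # % change of background rate
    fano_change_pc: float = 0.0  # % change of baseline-window Fano factor
    correlation_change_pc: float = 0.0  # % change of pairwise count correlation
    responsiveness_transitions: tuple | None = None  # (always, before_only,
    # after_only, never) proportions; None = responsive units stay responsive


@dataclass
class EnsembleSpec:
    """Statistical description of a synthetic recording ensemble."""

    n_units: int | None = None  # None: drawn as round(N(42, 8))
    baseline_rates: float | np.ndarray = 10.0  # Hz
    responsive_fraction: float = 0.5
    latency_range_ms: tuple = (5.0, 60.0)
    response_gain: float = 3.0  # peak rate as a multiple of baseline
    pairwise_correlation: float = 0.1  # target binned-count correlation
    fano_baseline: float = 1.3  # baseline-window Fano factor (20 ms)
    touch_rate_hz: float = 0.5
    effect: BeforeAfterEffect = field(default_factory=BeforeAfterEffect)

    def __post_init__(self) -> None:
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must be in [0, 1]")
        if np.any(np.asarray(self.baseline_rates) < 0):
            raise ValueError("rates must be >= 0")
        lo, hi = self.latency_range_ms
        if lo < 0 or hi > 70.0:
            raise ValueError("latencies must lie within the 0-70 ms window")
        if self.fano_baseline < 1.0:
            raise ValueError("fano_baseline below 1 is not constructible")


def generate_poisson_trains(
    rate_hz: float, n_trials: int, duration_s: float, seed: int | None = None
) -> list[np.ndarray]:
    """Homogeneous Poisson spike trains, one array per trial."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trials):
        n = rng.poisson(rate_hz * duration_s)
        out.append(np.sort(rng.uniform(0.0, duration_s, size=n)))
    return out


def generate_correlated_pair(
    rate_hz: float,
    correlation: float,
    bin_ms: float = 10.0,
    duration_s: float = 100.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two Poisson trains with the requested binned-count correlation.

    Shared-source construction: a common Poisson process contributes
    identical spikes to both trains, plus independent remainders.  At
    ``correlation=1`` the two trains are identical.
    """
    if not 0.0 <= correlation <= 1.0:
        raise ValueError("correlation target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_common = rng.poisson(correlation * rate_hz * duration_s)
    common = rng.uniform(0.0, duration_s, size=n_common)
    trains = []
    for _ in range(2):
        n_ind = rng.poisson((1.0 - correlation) * rate_hz * duration_s)
        ind = rng.uniform(0.0, duration_s, size=n_ind)
        trains.append(np.sort(np.concatenate([common, ind])))
    return trains[0], trains[1]


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------


def _smoothing_attenuation(kernel_sigma_ms: float = ANALYSIS_KERNEL_SIGMA_MS) -> float:
    """Amplitude attenuation of a Gaussian bump by the analysis kernel."""
    return BUMP_SIGMA_MS / np.hypot(BUMP_SIGMA_MS, kernel_sigma_ms)


def _gain_sd_for_fano(fano: float, lam_ind: np.ndarray, lam_tot: np.ndarray):
    """Per-unit gain SD g giving the requested Fano factor in the
    standard window: FF = 1 + g^2 * muI^2 / mu."""
    w = FANO_WINDOW_MS / 1000.0
    mu_ind = lam_ind * w
    mu = lam_tot * w
    if fano < 1.0:
        raise ValueError("Fano factor below 1 is not constructible")
    if fano == 1.0:
        return np.zeros_like(mu)
    if np.any(mu_ind <= 0):
        raise ValueError(
            "Fano factor above 1 requires a nonzero independent rate "
            "(reduce the correlation target)"
        )
    return np.sqrt((fano - 1.0) * mu / mu_ind**2)


def _phase_params(b, corr_target, fano, bin_ms):
    """Resolve shared-source and gain parameters for one phase.

    Returns (lam_common, q, lam_ind, gain_sd).  The correlation target
    is pre-compensated for gain dilution at the analysis bin size.
    """
    b = np.asarray(b, dtype=float)
    b_max = float(b.max())
    if b_max == 0:
        return 0.0, np.zeros_like(b), b.copy(), np.zeros_like(b)
    # iterate once: gain depends on lam_ind which depends on c_gen which
    # depends on the gain-diluted Fano at bin size
    c_gen = corr_target
    for _ in range(8):
        q = np.sqrt(np.clip(c_gen * b / b_max, 0.0, 1.0))
        lam_ind = b - q * b_max
        if np.any(lam_ind < -1e-9):
            raise ValueError(
                f"correlation target {corr_target} unachievable for the "
                "given rates/Fano factor"
            )
        lam_ind = np.clip(lam_ind, 0.0, None)
        g = _gain_sd_for_fano(fano, lam_ind, b) if fano > 1.0 else np.zeros_like(b)
        # Fano at the MI/correlation bin size dilutes correlation
        ff_bin = 1.0 + g**2 * (lam_ind * bin_ms / 1000.0) ** 2 / np.maximum(
            b * bin_ms / 1000.0, 1e-12
        )
        c_new = corr_target * float(np.sqrt(np.mean(ff_bin**2)))
        if abs(c_new - c_gen) < 1e-12:
            break
        c_gen = c_new
    if c_gen > 1.0:
        raise ValueError("compensated correlation target exceeds 1")
    return b_max, q, lam_ind, g


def _assign_types(n, spec, rng):
    eff = spec.effect
    if eff.responsiveness_transitions is not None:
        props = np.asarray(eff.responsiveness_transitions, dtype=float)
        if props.min() < 0 or not np.isclose(props.sum(), 1.0):
            raise ValueError("transition proportions must be >= 0 and sum to 1")
        counts = np.floor(props * n).astype(int)
        while counts.sum() < n:
            counts[np.argmax(props * n - counts)] += 1
        types = np.repeat(np.arange(4), counts)
    else:
        k = int(round(spec.responsive_fraction * n))
        types = np.array([0] * k + [3] * (n - k))
    rng.shuffle(types)
    return types  # 0 always, 1 before_only, 2 after_only, 3 never


def generate_session(
    spec: EnsembleSpec,
    durations_s=(180.0, 1800.0, 180.0),
    seed: int | None = None,
    bin_ms: float = 10.0,
) -> SessionRecording:
    """Generate one three-phase session realizing the ensemble's ground truth.

    The conditioning phase is silent (no touches, no spikes are
    modelled for it beyond background); the pre and post tactile phases
    realize the ensemble statistics, with every
    :class:`BeforeAfterEffect` field applied exactly (in expectation)
    to the post phase.
    """
    rng = np.random.default_rng(seed)
    d_pre, d_cond, d_post = (float(d) for d in durations_s)
    phases = [
        Phase("tactile_pre", 0.0, d_pre),
        Phase("conditioning", d_pre, d_pre + d_cond),
        Phase("tactile_post", d_pre + d_cond, d_pre + d_cond + d_post),
    ]
    n = spec.n_units
    if n is None:
        n = max(2, int(round(rng.normal(42.0, 8.0))))
    b_pre = np.broadcast_to(
        np.asarray(spec.baseline_rates, dtype=float), (n,)
    ).copy()
    eff = spec.effect
    types = _assign_types(n, spec, rng)
    latencies = rng.uniform(*spec.latency_range_ms, size=n)
    att = _smoothing_attenuation()
    # bump amplitude giving the requested peak multiple of baseline
    amp_pre = np.where(
        np.isin(types, (0, 1)), (spec.response_gain - 1.0) * b_pre, 0.0
    )

    # post-phase parameters from the injected effects
    b_post = b_pre * (1.0 + eff.baseline_gain_pc / 100.0)
    smoothed_peak_pre = b_pre + att * amp_pre
    target_peak_post = smoothed_peak_pre * (1.0 + eff.peak_gain_pc / 100.0)
    amp_post = np.where(
        np.isin(types, (0, 2)),
        np.maximum(target_peak_post - b_post, 0.0) / att,
        0.0,
    )
    # units gaining responsiveness get the ensemble-typical response
    newly = types == 2
    amp_post[newly] = (spec.response_gain - 1.0) * b_post[newly] * (
        1.0 + eff.peak_gain_pc / 100.0
    )
    fano_pre = spec.fano_baseline
    fano_post = 1.0 + (fano_pre - 1.0 + fano_pre * eff.fano_change_pc / 100.0)
    if fano_post < 1.0:
        raise ValueError("injected Fano change drops below the Poisson floor")
    corr_pre = spec.pairwise_correlation
    corr_post = corr_pre * (1.0 + eff.correlation_change_pc / 100.0)

    spike_times: dict[int, np.ndarray] = {i: [] for i in range(n)}
    events = []
    for ph, b, amp, fano, corr in (
        (phases[0], b_pre, amp_pre, fano_pre, corr_pre),
        (phases[2], b_post, amp_post, fano_post, corr_post),
    ):
        touches = (
            make_experimental_touch_schedule(
                ph.duration_s, spec.touch_rate_hz,
                seed=int(rng.integers(2**31 - 1)),
            )
            + ph.start_s
        )
        events.extend((t, "touch", "") for t in touches)
        lam_c, q, lam_ind, g = _phase_params(b, corr, fano, bin_ms)
        # shared source
        n_common = rng.poisson(lam_c * ph.duration_s)
        common = rng.uniform(ph.start_s, ph.end_s, size=n_common)
        # per-unit trains
        n_blocks = int(np.ceil(ph.duration_s / GAIN_BLOCK_S))
        for i in range(n):
            parts = []
            if q[i] > 0 and n_common:
                keep = rng.random(n_common) < q[i]
                parts.append(common[keep])
            if lam_ind[i] > 0:
                gains = (
                    rng.gamma(1.0 / g[i] ** 2, g[i] ** 2, size=n_blocks)
                    if g[i] > 0
                    else np.ones(n_blocks)
                )
                block_rate = lam_ind[i] * gains * GAIN_BLOCK_S
                counts = rng.poisson(block_rate)
                for k in np.flatnonzero(counts):
                    lo = ph.start_s + k * GAIN_BLOCK_S
                    hi = min(lo + GAIN_BLOCK_S, ph.end_s)
                    parts.append(rng.uniform(lo, hi, size=counts[k]))
            if amp[i] > 0:
                expected = amp[i] * (BUMP_SIGMA_MS / 1000.0) * np.sqrt(2 * np.pi)
                for t0 in touches:
                    nb = rng.poisson(expected)
                    if nb:
                        ts = (
                            t0
                            + latencies[i] / 1000.0
                            + rng.normal(0.0, BUMP_SIGMA_MS / 1000.0, size=nb)
                        )
                        parts.append(ts[(ts >= ph.start_s) & (ts < ph.end_s)])
            if parts:
                spike_times[i].append(np.concatenate(parts))
    for i in range(n):
        spike_times[i] = (
            np.sort(np.concatenate(spike_times[i]))
            if spike_times[i]
            else np.empty(0)
        )
    for ph in phases:
        events.append((ph.start_s, "phase_boundary", ph.label))
    events_df = pd.DataFrame(
        sorted(events), columns=["time_s", "event_type", "payload"]
    )
    positions = {
        i: tuple(xy) for i, xy in enumerate(rng.uniform(0, 1000.0, size=(n, 2)))
    }
    type_names = {0: "always", 1: "before_only", 2: "after_only", 3: "never"}
    return SessionRecording(
        spike_times=spike_times,
        events=events_df,
        phases=phases,
        unit_positions=positions,
        reference_unit=None,
        seed=seed,
        meta={
            "generator": "synthetic",
            "unit_types": {i: type_names[t] for i, t in enumerate(types)},
            "latencies_ms": latencies.tolist(),
        },
    )
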
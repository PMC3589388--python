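"""Information-theoretic dependence measures between spike trains.

Spike trains are binned (10 ms by default, which makes most bins 0 or 1
for rates around 10 Hz), binarized, and the mutual information between
unit pairs is estimated with the plug-in (empirical-distribution)
estimator.  The small-sample positive bias is removed by subtracting
the mean information of shuffled surrogates (random permutation of the
bins of one member of the pair).  Multi-information (total correlation)
generalizes this to small sub-ensembles: the sum of marginal entropies
minus the joint entropy, shuffle-corrected the same way.  Corrected
values are reported as-is and may be slightly negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import SessionRecording


@dataclass
class BinnedCounts:
    """Spike counts per unit per time bin over one phase."""

    counts: np.ndarray  # (n_units, n_bins) ints
    bin_ms: float
    unit_ids: list[int]

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    def binary(self) -> np.ndarray:
        return (self.counts > 0).astype(np.int64)


@dataclass
class InfoResult:
    """Bias-corrected pairwise MI (bits) and optional ensemble summaries."""

    mi_matrix: np.ndarray  # symmetric, NaN diagonal
    unit_ids: list[int]
    n_shuffles: int
    multi_info: float | None = None
    distances: np.ndarray | None = None  # um per pair, same shape as mi_matrix
    meta: dict = field(default_factory=dict)

    def pair_table(self):
        """Long-format (unit_a, unit_b, mi_bits[, distance_um]) table."""
        import pandas as pd

        rows = []
        n = len(self.unit_ids)
        for i in range(n):
            for j in range(i + 1, n):
                row = {
                    "unit_a": self.unit_ids[i],
                    "unit_b": self.unit_ids[j],
                    "mi_bits": self.mi_matrix[i, j],
                }
                if self.distances is not None:
                    row["distance_um"] = self.distances[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def bin_spike_counts(
    recording: SessionRecording,
    bin_ms: float = 10.0,
    phase: str = "tactile_pre",
    units=None,
) -> BinnedCounts:
    """Bin each unit's spikes within a phase; total counts are conserved
    except for spikes in the trailing partial bin."""
    ph = recording.phase(phase)
    n_bins = int(np.floor(ph.duration_s * 1000.0 / bin_ms))
    edges = ph.start_s + np.arange(n_bins + 1) * bin_ms / 1000.0
    unit_ids = list(units) if units is not None else recording.units
    counts = np.empty((len(unit_ids), n_bins), dtype=np.int64)
    for k, uid in enumerate(unit_ids):
        counts[k] = np.histogram(recording.spike_times[uid], bins=edges)[0]
    return BinnedCounts(counts=counts, bin_ms=bin_ms, unit_ids=unit_ids)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _codes(x: np.ndarray) -> tuple[np.ndarray, int]:
    vals, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes, len(vals)


def plugin_mi(x, y) -> float:
    """Plug-in mutual information (bits) of two equal-length discrete
    sequences: I = H(X) + H(Y) - H(X,Y) under empirical distributions."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    cx, kx = _codes(x)
    cy, ky = _codes(y)
    joint = np.bincount(cx * ky + cy, minlength=kx * ky)
    hx = _entropy_from_counts(np.bincount(cx, minlength=kx))
    hy = _entropy_from_counts(np.bincount(cy, minlength=ky))
    hxy = _entropy_from_counts(joint)
    return max(hx + hy - hxy, 0.0)


def shuffle_corrected_mi(
    x, y, n_shuffles: int = 20, seed: int | None = None
) -> float:
    """Bias-corrected MI: plug-in estimate minus the mean plug-in MI of
    surrogates in which the bins of one sequence are randomly permuted."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    x, y = np.asarray(x), np.asarray(y)
    raw = plugin_mi(x, y)
    rng = np.random.default_rng(seed)
    bias = np.mean(
        [plugin_mi(x, rng.permutation(y)) for _ in range(n_shuffles)]
    )
    return float(raw - bias)


def mi_matrix(
    counts: BinnedCounts,
    n_shuffles: int = 20,
    seed: int | None = None,
    positions: dict | None = None,
) -> InfoResult:
    """Shuffle-corrected MI for all unit pairs (binarized counts)."""
    if counts.n_units < 2:
        raise ValueError("need at least 2 units")
    xb = counts.binary()
    n = counts.n_units
    mat = np.full((n, n), np.nan)
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            v = shuffle_corrected_mi(
                xb[i], xb[j], n_shuffles=n_shuffles,
                seed=np.random.default_rng(pair_seeds[k]),
            )
            mat[i, j] = mat[j, i] = v
            k += 1
    dist = None
    if positions is not None:
        pos = np.array([positions[u] for u in counts.unit_ids], dtype=float)
        dist = np.hypot(
            pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1]
        )
        np.fill_diagonal(dist, np.nan)
    return InfoResult(
        mi_matrix=mat, unit_ids=counts.unit_ids, n_shuffles=n_shuffles,
        distances=dist,
    )


def multi_information(
    counts: BinnedCounts,
    subensemble_size: int = 5,
    n_subensembles: int = 50,
    n_shuffles: int = 20,
    seed: int | None = None,
) -> float:
    """Mean shuffle-corrected multi-information over random sub-ensembles.

    The multi-information of a sub-ensemble is the sum of the marginal
    entropies minus the joint entropy of the binarized counts; the
    shuffle correction permutes every member but the first
    independently.  The full-ensemble joint over dozens of units is not
    estimable, hence the sub-ensemble average.  At sub-ensemble size 2
    the statistic reduces exactly to pairwise MI.
    """
    if subensemble_size < 2:
        raise ValueError("subensemble_size must be >= 2")
    if subensemble_size > counts.n_units:
        raise ValueError("subensemble_size exceeds the number of units")
    xb = counts.binary()
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_subensembles):
        members = rng.choice(counts.n_units, size=subensemble_size, replace=False)
        sub = xb[members]
        if subensemble_size == 2:
            # route through the pairwise estimator so the definitional
            # reduction to MI is exact, shuffles included
            values.append(
                shuffle_corrected_mi(
                    sub[0], sub[1], n_shuffles=n_shuffles,
                    seed=np.random.default_rng(rng.integers(2**31 - 1)),
                )
            )
            continue
        raw = _total_correlation(sub)
        bias = []
        for _ in range(n_shuffles):
            surrogate = sub.copy()
            for m in range(1, subensemble_size):
                surrogate[m] = rng.permutation(surrogate[m])
            bias.append(_total_correlation(surrogate))
        values.append(raw - float(np.mean(bias)))
    return float(np.mean(values))


def _total_correlation(xb: np.ndarray) -> float:
    """Sum of marginal entropies minus joint entropy of binary rows."""
    k, n = xb.shape
    marg = sum(
        _entropy_from_counts(np.bincount(xb[m], minlength=2)) for m in range(k)
    )
    codes = np.zeros(n, dtype=np.int64)
    for m in range(k):
        codes = codes * 2 + xb[m]
    joint = _entropy_from_counts(np.bincount(codes, minlength=2**k))
    return marg - joint


def mi_vs_distance(info: InfoResult, bin_edges_um=None):
    """Per-pair (distance, MI) table plus a binned mean-MI curve.

    Returns ``(table, bin_centers, bin_means)``.
    """
    if info.distances is None:
        raise ValueError("no positions/distances available")
    if bin_edges_um is None:
        bin_edges_um = np.arange(0.0, 1500.0 + 1e-9, 100.0)
    tab = info.pair_table()
    d = tab["distance_um"].to_numpy()
    mi = tab["mi_bits"].to_numpy()
    idx = np.digitize(d, bin_edges_um) - 1
    centers = (np.asarray(bin_edges_um[:-1]) + np.asarray(bin_edges_um[1:])) / 2.0
    means = np.array(
        [mi[idx == k].mean() if np.any(idx == k) else np.nan
         for k in range(len(centers))]
    )
    return tab, centers, means


def trigger_pair_contrast(
    info_before: InfoResult, info_after: InfoResult, reference_unit: int
):
    """Fraction of pairs with increased MI, split by whether the pair
    contains the spike-trigger reference unit.

    Returns a dict with the two proportions plus the per-pair MI deltas
    for rank-based testing.
    """
    if reference_unit not in info_before.unit_ids:
        raise ValueError("reference unit not in the ensemble")
    if info_before.unit_ids != info_after.unit_ids:
        raise ValueError("unit sets differ")
    ids = info_before.unit_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 units")
    ref_k = ids.index(reference_unit)
    trig_delta, non_delta = [], []
    for i in range(n):
        for j in range(i + 1, n):
            delta = info_after.mi_matrix[i, j] - info_before.mi_matrix[i, j]
            (trig_delta if ref_k in (i, j) else non_delta).append(delta)
    trig_delta = np.asarray(trig_delta)
    non_delta = np.asarray(non_delta)
    return {
        "trigger_increase_frac": float(np.mean(trig_delta > 0)),
        "nontrigger_increase_frac": float(np.mean(non_delta > 0)),
        "trigger_deltas": trig_delta,
        "nontrigger_deltas": non_delta,
    }


def crosscorrelogram(
    x,
    y,
    duration_s: float,
    maxlag_ms: float = 100.0,
    bin_ms: float = 1.0,
    n_shuffles: int = 20,
    seed: int | None = None,
):
    """Normalized spike-train crosscorrelogram with shuffle bounds.

    The histogram of pairwise lags (y relative to x) is normalized by
    the rate-expected count, so independent trains fluctuate around 1.
    The 95% bounds come from surrogates in which y is circularly shifted
    by a random offset.

    Returns ``(lag_centers_ms, correlogram, lower, upper)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("spike trains must be non-empty")
    edges = np.arange(-maxlag_ms, maxlag_ms + bin_ms, bin_ms) / 1000.0
    centers = (edges[:-1] + edges[1:]) / 2.0 * 1000.0
    expected = len(x) * len(y) * (bin_ms / 1000.0) / duration_s

    def corr(yy):
        lags = []
        lo = np.searchsorted(yy, x - maxlag_ms / 1000.0)
        hi = np.searchsorted(yy, x + maxlag_ms / 1000.0)
        for k, t in enumerate(x):
            lags.append(yy[lo[k]:hi[k]] - t)
        lags = np.concatenate(lags) if lags else np.empty(0)
        return np.histogram(lags, bins=edges)[0] / expected

    cgram = corr(y)
    rng = np.random.default_rng(seed)
    surr = np.empty((n_shuffles, len(centers)))
    for s in range(n_shuffles):
        shift = rng.uniform(0.0, duration_s)
        surr[s] = corr(np.sort((y + shift) % duration_s))
    lower = np.percentile(surr, 2.5, axis=0)
    upper = np.percentile(surr, 97.5, axis=0)
    return centers, cgram, lower, upper


def correlation_matrix(
    counts: BinnedCounts, n_shuffles: int = 100, seed: int | None = None
):
    """Pearson correlation of binned counts per pair, with a shuffle
    significance flag (|r| above the 95th percentile of permuted |r|).

    Returns ``(r_matrix, significant)``; zero-variance units give NaN.
    """
    if counts.n_units < 2:
        raise ValueError("need at least 2 units")
    x = counts.counts.astype(float)
    n = counts.n_units
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    np.fill_diagonal(r, np.nan)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    rng = np.random.default_rng(seed)
    sig = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(r[i, j]):
                continue
            null = np.empty(n_shuffles)
            for s in range(n_shuffles):
                null[s] = abs(_pearson(x[i], rng.permutation(x[j])))
            thresh = np.percentile(null, 95.0)
            sig[i, j] = sig[j, i] = abs(r[i, j]) > thresh
    return r, sig


def _pearson(a, b) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else np.nan


def mean_pair_mi(info: InfoResult) -> float:
    """Mean corrected MI over unordered pairs (the per-session summary)."""
    iu = np.triu_indices_from(info.mi_matrix, k=1)
    return float(np.nanmean(info.mi_matrix[iu]))
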
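"""Before/after comparison statistics across sessions.

The effect-size currency is the percentage change
PC = 100 x (after - before) / before.  Session-level inference uses the
Wilcoxon signed-rank test on paired per-session values, pooled
distributions are compared with a two-sample Kolmogorov-Smirnov test,
and per-session pair-level increases are assessed with a bootstrap CI
of the mean difference.  Sessions are pooled as independent
observations and no multiple-testing correction is applied by default
(a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class SessionComparison:
    metric: str
    before: float
    after: float
    pc: float  # percent change of the means
    test: str
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def percent_change(before: float, after: float) -> float:
    """PC = 100 x (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for a zero 'before' value")
    return 100.0 * (after - before) / before


def session_level_tests(
    per_session_pairs, alpha: float = ALPHA, metric: str = ""
) -> SessionComparison:
    """Wilcoxon signed-rank test on paired per-session (before, after)
    values; reports the PC of the means."""
    pairs = np.asarray(per_session_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("need >= 2 (before, after) pairs")
    before, after = pairs[:, 0], pairs[:, 1]
    diff = after - before
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(before, after).pvalue)
    return SessionComparison(
        metric=metric,
        before=float(before.mean()),
        after=float(after.mean()),
        pc=percent_change(before.mean(), after.mean()),
        test="wilcoxon_signed_rank",
        p_value=p,
        n=len(pairs),
    )


def pooled_distribution_test(before_values, after_values) -> float:
    """Two-sample Kolmogorov-Smirnov p-value on pooled distributions."""
    b = np.asarray(before_values, dtype=float)
    a = np.asarray(after_values, dtype=float)
    if b.size == 0 or a.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(b, a).pvalue)


def bootstrap_increase_test(
    pair_values_before,
    pair_values_after,
    n_boot: int = 100,
    seed: int | None = None,
    ci: float = 95.0,
):
    """Bootstrap CI of the mean paired difference (after - before).

    Returns ``(lower, upper, significant)``; significant iff the CI
    excludes zero.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    b = np.asarray(pair_values_before, dtype=float)
    a = np.asarray(pair_values_after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after pair lists must match")
    diff = a - b
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
    means = diff[idx].mean(axis=1)
    lo = float(np.percentile(means, (100.0 - ci) / 2.0))
    hi = float(np.percentile(means, 100.0 - (100.0 - ci) / 2.0))
    return lo, hi, bool(lo > 0.0 or hi < 0.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank, k in enumerate(reversed(order), start=0):
        i = m - rank
        prev = min(prev, p[k] * m / i)
        adj[k] = prev
    return adj


def build_report(
    pre: dict[str, np.ndarray],
    post: dict[str, np.ndarray],
    adjust: bool = False,
) -> pd.DataFrame:
    """Tabulate before/after means, PCs and Wilcoxon p per metric.

    ``pre`` and ``post`` map metric names to matched per-session (or
    per-unit) value arrays.  Set ``adjust=True`` for Benjamini-Hochberg
    adjusted p-values in an extra column.
    """
    if set(pre) != set(post):
        raise ValueError("metric sets differ between pre and post bundles")
    rows = []
    for metric in pre:
        b = np.asarray(pre[metric], dtype=float)
        a = np.asarray(post[metric], dtype=float)
        if b.shape != a.shape:
            raise ValueError(f"{metric}: mismatched pre/post lengths")
        comp = session_level_tests(np.column_stack([b, a]), metric=metric)
        rows.append(
            {
                "metric": metric,
                "before": comp.before,
                "after": comp.after,
                "pc": comp.pc,
                "test": comp.test,
                "p_value": comp.p_value,
                "n": comp.n,
            }
        )
    report = pd.DataFrame(rows)
    if adjust:
        report["p_adjusted"] = benjamini_hochberg(report["p_value"].to_numpy())
    return report
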
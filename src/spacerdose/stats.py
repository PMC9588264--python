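"""Cohort statistics: paired permutation tests and boxplot summaries.

Scenario comparisons are paired within each case (every phantom is planned
once and recalculated under each material scenario), so the exchangeable
null is a random sign flip of each case's paired difference. The test
statistic is the mean paired difference; p-values are two-sided. When the
full 2^n sign-flip set is small it is enumerated exactly; otherwise n_perm
random flips are drawn with the add-one Monte Carlo estimator
p = (1 + #{|T*| >= |T|}) / (n_perm + 1), which respects the 1/(n_perm + 1)
lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PermutationResult:
    observed: float      # mean paired difference
    n_perm: int          # permutations actually used (2^n when exhaustive)
    p_value: float       # two-sided
    exhaustive: bool
    seed: int | None


def paired_permutation_test(
    differences,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = 4096,
) -> PermutationResult:
    """Two-sided sign-flip permutation test on paired differences."""
    d = np.asarray(differences, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = abs(d.mean())
    n = d.size
    if 2**n <= exhaustive_limit:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        t_null = np.abs((signs * d).mean(axis=1))
        p = float((t_null >= t_obs - 1e-12 * max(t_obs, 1.0)).sum()) / 2**n
        return PermutationResult(float(d.mean()), 2**n, p, True, None)
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_null = np.abs((signs * d).mean(axis=1))
    p = (1.0 + float((t_null >= t_obs - 1e-12 * max(t_obs, 1.0)).sum())) / (n_perm + 1.0)
    return PermutationResult(float(d.mean()), n_perm, p, False, seed)


@dataclass(frozen=True)
class BoxStats:
    """Boxplot summary: median, quartiles, 1.5-IQR whiskers at data points."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def box_summary(values) -> BoxStats:
    """Quartiles by linear interpolation; whiskers at the most extreme data
    within 1.5 IQR of the box; everything beyond is an outlier."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])),
    )


def multiple_comparison_annotation(
    p_values, labels=None, bh: bool = False, alpha: float = 0.05
) -> pd.DataFrame:
    """Raw p-values with ranks; optional Benjamini-Hochberg column (off by
    default — the primary report uses raw p-values)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    df = pd.DataFrame({
        "label": labels if labels is not None else [f"test{i}" for i in range(p.size)],
        "p_value": p,
    })
    df["rank"] = df["p_value"].rank(method="first").astype(int)
    if bh:
        reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        df["p_bh"] = p_adj
        df["significant_bh"] = reject
    return df
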